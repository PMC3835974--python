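{
  "version": 1,
  "comment": "Best-fit parameter sets of the CD and triplet rules for the four induction datasets (VC5: visual cortex L5; HC: cultured hippocampal neurons; SC23: somatosensory cortex L2/3; VC23: visual cortex L2/3). Times in seconds; 'provenance' keeps the printed strings including absent ('-') entries. theta_q null means a negative threshold (activation gate always open). published_error is reference metadata only: it depends on unpublished experimental measurements.",
  "cd": {
    "VC5": {
      "params": {"tau_pre": 0.014, "tau_post": 0.042, "tau_rec_pre": 0.094, "c_pre": 0.7, "tau_rec_post": 1.0, "c_post": 0.0, "q_min": 0.25, "tau_q": 0.046, "c_q": 1.93, "theta_q": null, "c_w": 0.03},
      "published_error": 0.17,
      "provenance": {"tau_pre": "14 ms", "tau_post": "42 ms", "tau_rec_pre": "94 ms", "c_pre": "0.7", "tau_rec_post": "-", "c_post": "0", "q_min": "0.25", "tau_q": "46 ms", "c_q": "1.93", "theta_q": "< 0", "c_w": "0.03"},
      "notes": "tau_rec_post not printed; stored as an inert 1 s since c_post = 0 disables postsynaptic adaptation."
    },
    "HC": {
      "params": {"tau_pre": 0.017, "tau_post": 0.034, "tau_rec_pre": 3.0, "c_pre": 0.2, "tau_rec_post": 0.01, "c_post": 0.9, "q_min": 1.0, "tau_q": 0.02, "c_q": 3.0, "theta_q": null, "c_w": 0.009},
      "published_error": 2.81,
      "provenance": {"tau_pre": "17 ms", "tau_post": "34 ms", "tau_rec_pre": "3 s", "c_pre": "0.2", "tau_rec_post": "10 ms", "c_post": "0.9", "q_min": "1", "tau_q": "20 ms", "c_q": "3.0", "theta_q": "< 0", "c_w": "0.009"},
      "notes": "tau_rec_pre sits at the upper search bound; stored verbatim."
    },
    "SC23": {
      "params": {"tau_pre": 0.014, "tau_post": 0.042, "tau_rec_pre": 1.0, "c_pre": 0.0, "tau_rec_post": 0.02, "c_post": 1.0, "q_min": 0.25, "tau_q": 0.5, "c_q": 8.5, "theta_q": 0.1, "c_w": 0.018},
      "published_error": 0.81,
      "provenance": {"tau_pre": "14 ms", "tau_post": "42 ms", "tau_rec_pre": "-", "c_pre": "-", "tau_rec_post": "20 ms", "c_post": "1", "q_min": "0.25", "tau_q": "0.5 s", "c_q": "8.5", "theta_q": "0.1", "c_w": "0.018"},
      "notes": "Single presynaptic spike per pattern: presynaptic adaptation unidentifiable, fixed c_pre = 0 (u_pre = 1); tau_rec_pre stored as an inert 1 s."
    },
    "VC23": {
      "params": {"tau_pre": 0.014, "tau_post": 0.042, "tau_rec_pre": 0.6, "c_pre": 0.7, "tau_rec_post": 0.3, "c_post": 0.9, "q_min": 1.0, "tau_q": 0.3, "c_q": 6.6, "theta_q": 0.1, "c_w": 0.033},
      "published_error": 0.78,
      "provenance": {"tau_pre": "14 ms", "tau_post": "42 ms", "tau_rec_pre": "0.6 s", "c_pre": "0.7", "tau_rec_post": "0.3 s", "c_post": "0.9", "q_min": "1", "tau_q": "0.3 s", "c_q": "6.6", "theta_q": "0.1", "c_w": "0.033"}
    }
  },
  "triplet": {
    "VC5": {
      "params": {"tau_plus": 0.017, "tau_minus": 0.034, "tau_x": null, "tau_y": 0.038, "A2_plus": 0.0, "A3_plus": 0.049, "A2_minus": 0.0068, "A3_minus": 0.0, "mode": "nearest_neighbor"},
      "published_error": 0.33,
      "provenance": {"tau_plus": "17 ms", "tau_minus": "34 ms", "tau_x": "-", "tau_y": "38 ms", "A2_plus": "0", "A3_plus": "0.049", "A2_minus": "0.0068", "A3_minus": "0"},
      "notes": "tau_x absent together with A3_minus = 0; re-fit preferred nearest-neighbor interactions (all-to-all error 0.51)."
    },
    "HC": {
      "params": {"tau_plus": 0.017, "tau_minus": 0.034, "tau_x": 0.946, "tau_y": 0.027, "A2_plus": 0.0061, "A3_plus": 0.0067, "A2_minus": 0.0016, "A3_minus": 0.0014, "mode": "all_to_all"},
      "published_error": 2.9,
      "provenance": {"tau_plus": "17 ms", "tau_minus": "34 ms", "tau_x": "946 ms", "tau_y": "27 ms", "A2_plus": "0.0061", "A3_plus": "0.0067", "A2_minus": "0.0016", "A3_minus": "0.0014"},
      "notes": "Published all-to-all hippocampal set."
    },
    "SC23": {
      "params": {"tau_plus": 0.014, "tau_minus": 0.042, "tau_x": 7.7, "tau_y": 0.006, "A2_plus": 0.006, "A3_plus": 0.211, "A2_minus": 0.0004, "A3_minus": 0.009, "mode": "all_to_all"},
      "published_error": 1.69,
      "provenance": {"tau_plus": "14 ms", "tau_minus": "42 ms", "tau_x": "7.7 s", "tau_y": "6 ms", "A2_plus": "0.006", "A3_plus": "0.211", "A2_minus": "0.0004", "A3_minus": "0.009"},
      "notes": "All-to-all interactions gave the smaller error (1.69 vs 1.97)."
    },
    "VC23": {
      "params": {"tau_plus": 0.014, "tau_minus": 0.042, "tau_x": 2.7, "tau_y": 2.6, "A2_plus": 0.007, "A3_plus": -0.0005, "A2_minus": 0.0104, "A3_minus": 0.01, "mode": "nearest_neighbor"},
      "published_error": 2.78,
      "provenance": {"tau_plus": "14 ms", "tau_minus": "42 ms", "tau_x": "2.7 s", "tau_y": "2.6 s", "A2_plus": "0.007", "A3_plus": "-0.0005", "A2_minus": "0.0104", "A3_minus": "0.01"},
      "notes": "Nearest-neighbor interactions (25% lower error than all-to-all); negative A3_plus mimics adaptation."
    }
  },
  "bounds": {
    "cd": {
      "tau_rec_pre": [0.001, 3.0],
      "c_pre": [0.0, 1.0],
      "tau_rec_post": [0.001, 3.0],
      "c_post": [0.0, 1.0],
      "tau_q": [0.001, 3.0],
      "c_q": [0.0, 10.0],
      "theta_q": [0.0, 0.2],
      "c_w": [0.001, 0.1]
    },
    "triplet": {
      "tau_x": [0.0001, 5.0],
      "tau_y": [0.0001, 5.0],
      "A2_plus": [0.0, 0.1],
      "A3_plus": [-0.1, 0.1],
      "A2_minus": [0.0, 0.1],
      "A3_minus": [-0.1, 0.1]
    }
  }
}
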