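"""Oscillatory susceptibility: closed form, Monte Carlo, mean field."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from synplast import (CDParams, OscillationSpec, PairStdpParams,
                      SusceptibilitySurface, ablate_cd, amplitude_sweep,
                      analytic_surface, f_max, load_params, malleability,
                      mc_susceptibility_surface, mean_field_y_infinity,
                      rate_profile, sample_poisson_train,
                      spstdp_susceptibility_analytic, with_updates)


def quadrature_oracle(params, spec):
    """Independent oracle: solve the mean-trace ODEs driven by the sinusoidal
    rates and average the drift over one period after transients."""
    w = 2 * math.pi * spec.f_mod
    rb, eps, dphi = spec.r_base, spec.epsilon, spec.delta_phi
    rpre = lambda t: rb * (1 + eps * np.cos(w * t))
    rpost = lambda t: rb * (1 + eps * np.cos(w * t - dphi))
    rhs = lambda t, y: [-y[0] / params.tau_pre + rpre(t),
                        -y[1] / params.tau_post + rpost(t)]
    T = 1.0 / spec.f_mod
    t1 = 2.0
    sol = solve_ivp(rhs, [0, t1 + T], [0, 0], rtol=1e-10, atol=1e-12,
                    dense_output=True)
    ts = np.linspace(t1, t1 + T, 4001)
    ypre, ypost = sol.sol(ts)
    wdot = params.c_w * (params.q * ypre * rpost(ts)
                         - ypre * ypost / params.tau_post)
    return np.trapezoid(wdot, ts) / T


def _spec(f_mod, dphi, r_base=5.0, epsilon=1.0, **kw):
    kw.setdefault("duration", 22.0)
    return OscillationSpec(r_base=r_base, f_mod=f_mod, delta_phi=dphi,
                           epsilon=epsilon, **kw)


class TestRateProfile:
    def test_no_modulation_is_flat(self):
        spec = _spec(5.0, 1.0, epsilon=0.0)
        ts = np.linspace(0, 1, 50)
        np.testing.assert_allclose(rate_profile(spec, "pre", ts), 5.0)

    def test_presynaptic_peak_at_zero(self):
        spec = _spec(5.0, 1.0)
        assert rate_profile(spec, "pre", 0.0) == pytest.approx(10.0)

    def test_postsynaptic_peak_lags_by_phase(self):
        spec = _spec(5.0, 1.2)
        t_peak = spec.delta_phi / (2 * math.pi * spec.f_mod)
        assert rate_profile(spec, "post", t_peak) == pytest.approx(10.0)


class TestPoissonSampling:
    def test_counts_concentrate_around_rate_times_duration(self):
        spec = _spec(1.0, 0.0, r_base=20.0, epsilon=0.0, duration=10.0)
        expected = 20.0 * 10.0
        for seed in range(20):
            n = len(sample_poisson_train(spec, "pre", seed))
            assert abs(n - expected) < 4 * math.sqrt(expected)

    def test_zero_rate_gives_empty_train(self):
        spec = _spec(1.0, 0.0, r_base=0.0, epsilon=0.0, duration=5.0)
        assert len(sample_poisson_train(spec, "pre", 0)) == 0

    def test_seed_reproducibility(self):
        spec = _spec(5.0, 0.5, duration=5.0)
        a = sample_poisson_train(spec, "post", 123)
        b = sample_poisson_train(spec, "post", 123)
        c = sample_poisson_train(spec, "post", 124)
        np.testing.assert_array_equal(a.times, b.times)
        assert len(c) == 0 or not np.array_equal(a.times, c.times)

    def test_overfull_bins_rejected(self):
        with pytest.raises(ValueError):
            OscillationSpec(r_base=6000.0, f_mod=5.0, duration=1.0, dt=1e-3)


class TestFmax:
    def test_vc23_and_hc_window_constants(self):
        assert f_max(0.014, 0.042) == pytest.approx(6.56, abs=0.005)
        assert f_max(0.017, 0.034) == pytest.approx(6.62, abs=0.005)

    def test_equal_time_constants(self):
        tau = 0.02
        assert f_max(tau, tau) == pytest.approx(1 / (2 * math.pi * tau))

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            f_max(0.0, 0.042)


class TestAnalyticSusceptibility:
    @pytest.mark.parametrize("q,f_mod,dphi", [
        (1.0, 6.0, 0.5), (1.0, 2.0, -1.0), (1.4, 6.56, 0.0),
        (0.7, 20.0, 2.0), (1.0, 1.0, 3.0)])
    def test_matches_quadrature_oracle(self, q, f_mod, dphi):
        p = PairStdpParams(0.014, 0.042, q=q, c_w=1.0)
        spec = _spec(f_mod, dphi)
        assert spstdp_susceptibility_analytic(p, spec) == pytest.approx(
            quadrature_oracle(p, spec), rel=1e-8, abs=1e-12)

    def test_balanced_rule_without_modulation_is_null(self, pair_vc23):
        spec = _spec(5.0, 0.7, epsilon=0.0)
        assert spstdp_susceptibility_analytic(pair_vc23, spec) == pytest.approx(0.0, abs=1e-15)

    def test_phase_periodicity_exact(self, pair_vc23):
        a = spstdp_susceptibility_analytic(pair_vc23, _spec(6.0, 0.8))
        b = spstdp_susceptibility_analytic(pair_vc23, _spec(6.0, 0.8 + 2 * math.pi))
        assert a == pytest.approx(b, rel=1e-12)

    def test_band_pass_rolloff_is_first_order(self, pair_vc23):
        """The balanced surface decays ~f below and ~1/f above the peak
        (20 dB/decade); both extremes sit far below the peak value."""
        phases = np.linspace(0, 2 * math.pi, 32, endpoint=False)
        peak = max(abs(spstdp_susceptibility_analytic(pair_vc23, _spec(6.56, ph)))
                   for ph in phases)
        lo = max(abs(spstdp_susceptibility_analytic(pair_vc23, _spec(1e-3, ph)))
                 for ph in phases)
        hi = max(abs(spstdp_susceptibility_analytic(pair_vc23, _spec(1e4, ph)))
                 for ph in phases)
        assert lo < 1e-2 * peak
        assert hi < 1e-2 * peak
        # adjacent decades sit a factor ~4 below the peak; the next decade a
        # further factor ~10 (first-order skirts on both sides)
        mal = malleability(analytic_surface(
            pair_vc23, [0.0656, 0.656, 6.56, 65.6, 656.0], phases))
        assert mal[2] == max(mal)
        assert mal[1] < 0.25 * mal[2] and mal[3] < 0.25 * mal[2]
        assert mal[0] < 0.15 * mal[1] and mal[4] < 0.15 * mal[3]

    def test_biased_rules_keep_phase_dependence_at_low_frequency(self):
        """Strong LTP/LTD bias turns the band-pass into a low-pass: the
        phase spread no longer vanishes as f_mod -> 0."""
        phases = np.linspace(0, 2 * math.pi, 16, endpoint=False)
        biased = PairStdpParams(0.014, 0.042, q=2.0, c_w=1.0)
        spread = malleability(analytic_surface(biased, [1e-3, 6.56], phases))
        assert spread[0] > 0.3 * spread[1]


class TestMonteCarloSurface:
    def test_matches_analytic_within_errorbars(self, pair_vc23):
        f_mod = [2.0, 6.0, 16.0]
        phases = np.linspace(-np.pi, np.pi, 4, endpoint=False)
        surf = mc_susceptibility_surface("spstdp", pair_vc23, f_mod, phases,
                                         r_base=5.0, window=20.0,
                                         n_realizations=40, seed=10)
        ana = analytic_surface(pair_vc23, f_mod, phases, r_base=5.0)
        z = (surf.mean - ana.mean) / surf.se
        assert np.all(np.abs(z) < 4.0)
        assert np.mean(np.abs(z) < 3.0) >= 0.9

    def test_zero_rate_gives_zero_surface(self, pair_vc23):
        surf = mc_susceptibility_surface("spstdp", pair_vc23, [2.0, 5.0],
                                         [-1.0, 0.0, 1.0], r_base=0.0,
                                         window=5.0, n_realizations=3, seed=0)
        np.testing.assert_array_equal(surf.mean, 0.0)

    def test_balanced_null_with_flat_rates(self, pair_vc23):
        surf = mc_susceptibility_surface("spstdp", pair_vc23, [5.0], [0.0],
                                         r_base=5.0, epsilon=0.0, window=20.0,
                                         n_realizations=40, seed=11)
        assert abs(surf.mean[0, 0]) < 3 * surf.se[0, 0]

    def test_phase_periodicity_within_errorbars(self, pair_vc23):
        surf = mc_susceptibility_surface(
            "spstdp", pair_vc23, [6.0], [0.5, 0.5 + 2 * math.pi],
            r_base=5.0, window=20.0, n_realizations=40, seed=12)
        diff = abs(surf.mean[0, 0] - surf.mean[0, 1])
        joint = math.hypot(surf.se[0, 0], surf.se[0, 1])
        assert diff < 3 * joint

    def test_cell_substreams_allow_resume(self, pair_vc23):
        f_mod = [2.0, 6.0]
        phases = [0.0, 1.0]
        full = mc_susceptibility_surface("spstdp", pair_vc23, f_mod, phases,
                                         r_base=5.0, window=5.0,
                                         n_realizations=5, seed=3)
        partial = SusceptibilitySurface(
            np.asarray(f_mod), np.asarray(phases),
            np.where([[True, False], [False, True]], full.mean, np.nan),
            np.where([[True, False], [False, True]], full.se, np.nan))
        resumed = mc_susceptibility_surface("spstdp", pair_vc23, f_mod, phases,
                                            r_base=5.0, window=5.0,
                                            n_realizations=5, seed=3,
                                            resume_from=partial)
        np.testing.assert_allclose(resumed.mean, full.mean)
        np.testing.assert_allclose(resumed.se, full.se)

    def test_bad_window_rejected(self, pair_vc23):
        with pytest.raises(ValueError):
            mc_susceptibility_surface("spstdp", pair_vc23, [5.0], [0.0],
                                      r_base=5.0, window=0.0, n_realizations=2)

    def test_cd_theta_band_potentiation_at_small_positive_phase(self):
        """SC23 parameters (with the VC23 presynaptic-adaptation values):
        maximal potentiation in the 2-10 Hz band at zero-to-small-positive
        phase shifts, at a 5 Hz baseline rate."""
        p = with_updates(load_params("SC23", "cd").params,
                         tau_rec_pre=0.6, c_pre=0.7)
        f_mod = [1.0, 2.0, 3.0, 5.0, 7.0, 10.0, 20.0, 40.0]
        phases = np.linspace(-np.pi, np.pi, 8, endpoint=False)
        surf = mc_susceptibility_surface("cd", p, f_mod, phases, r_base=5.0,
                                         window=20.0, n_realizations=20, seed=21)
        i, j = np.unravel_index(np.argmax(surf.mean), surf.mean.shape)
        assert 2.0 <= surf.f_mod[i] <= 10.0
        assert -np.pi / 4 <= surf.delta_phi[j] <= np.pi / 2


class TestAblation:
    def test_ablating_zero_component_is_identity(self):
        p = load_params("SC23", "cd").params  # c_pre already 0
        assert ablate_cd(p, "pre_adaptation") == p

    def test_double_ablation_commutes(self):
        p = load_params("VC23", "cd").params
        a = ablate_cd(ablate_cd(p, "pre_adaptation"), "activation")
        b = ablate_cd(ablate_cd(p, "activation"), "pre_adaptation")
        assert a == b

    def test_unknown_component_rejected(self):
        with pytest.raises(ValueError):
            ablate_cd(load_params("SC23", "cd").params, "dendrite")

    def test_no_activation_makes_sc23_depress_everywhere(self):
        """Removing the activation leaves the depression-biased window
        (q = q_min = 0.25): the surface is negative throughout."""
        p = ablate_cd(load_params("SC23", "cd").params, "activation")
        surf = mc_susceptibility_surface("cd", p, [2.0, 5.0, 10.0],
                                         [-2.0, 0.0, 2.0], r_base=5.0,
                                         window=20.0, n_realizations=20, seed=22)
        assert np.all(surf.mean <= 3 * surf.se)


class TestMeanField:
    def test_high_rate_limit_vc23(self):
        assert mean_field_y_infinity(0.014, 0.7, 0.6, math.inf) == pytest.approx(
            0.033, abs=5e-4)

    def test_zero_rate_gives_zero(self):
        assert mean_field_y_infinity(0.02, 0.5, 0.3, 0.0) == 0.0

    def test_monotone_in_rate_with_supremum_at_infinity(self):
        rates = [1.0, 5.0, 20.0, 100.0, 1000.0]
        vals = [mean_field_y_infinity(0.014, 0.7, 0.6, r) for r in rates]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < mean_field_y_infinity(0.014, 0.7, 0.6, math.inf)

    def test_infinite_rate_without_adaptation_rejected(self):
        with pytest.raises(ValueError):
            mean_field_y_infinity(0.014, 0.0, 0.6, math.inf)

    def test_matches_simulated_trace_average(self):
        """Time-averaged y_pre from constant-rate Poisson simulations agrees
        with the finite-rate mean-field formula."""
        from synplast import simulate_cd
        tau, c, tau_rec, rate = 0.014, 0.5, 0.3, 40.0
        p = CDParams(tau_pre=tau, tau_post=0.042, tau_rec_pre=tau_rec,
                     tau_rec_post=0.1, c_pre=c, c_post=0.0, q_min=1.0,
                     tau_q=0.1, c_q=0.0, theta_q=2.0, c_w=1.0)
        spec = OscillationSpec(r_base=rate, f_mod=1.0, epsilon=0.0,
                               duration=60.0)
        estimates = []
        for seed in range(8):
            pre = sample_poisson_train(spec, "pre", seed)
            post = sample_poisson_train(spec, "post", 1000 + seed)
            traj = simulate_cd(pre, post, p, t_end=spec.duration,
                               record=True).trajectory
            # integral of y over the run from the trace identity:
            # y(T) - y(0) = -int(y)/tau + sum of increments u(t-0)
            pre_rows = traj["t"].isin(pre.times)
            incr = (traj.loc[pre_rows, "u_pre"] / (1 - c)).sum()
            y_T = traj["y_pre"].iloc[-1] * math.exp(
                -(spec.duration - traj["t"].iloc[-1]) / tau)
            estimates.append(tau * (incr - y_T) / spec.duration)
        mf = mean_field_y_infinity(tau, c, tau_rec, rate)
        se = np.std(estimates, ddof=1) / math.sqrt(len(estimates))
        assert abs(np.mean(estimates) - mf) < 3 * se + 0.02 * mf


class TestAmplitudeSweep:
    def test_unmodulated_column_equals_constant_rate_estimate(self, pair_vc23):
        table = amplitude_sweep("spstdp", pair_vc23, [5.0], [0.0, 1.0],
                                f_mod=5.0, delta_phi=0.0, window=10.0,
                                n_realizations=10, seed=5)
        eps0 = table[table.epsilon == 0.0].iloc[0]
        ana0 = spstdp_susceptibility_analytic(
            pair_vc23, _spec(5.0, 0.0, epsilon=0.0))
        assert abs(eps0["mean"] - ana0) < 4 * eps0["se"]

    def test_balanced_rule_cells_match_analytic(self, pair_vc23):
        table = amplitude_sweep("spstdp", pair_vc23, [5.0, 10.0], [0.5, 1.0],
                                f_mod=5.0, delta_phi=0.0, window=20.0,
                                n_realizations=30, seed=6)
        for _, row in table.iterrows():
            ana = spstdp_susceptibility_analytic(
                pair_vc23, _spec(5.0, 0.0, r_base=row.r_base, epsilon=row.epsilon))
            assert abs(row["mean"] - ana) < 4 * row["se"]

    def test_sc23_modulation_boosts_weight_change(self):
        """Theta modulation increases the weight-change rate of the SC23
        synapse at elevated baseline rates (trend within MC error)."""
        p = load_params("SC23", "cd").params
        table = amplitude_sweep("cd", p, [10.0], [0.0, 1.0], f_mod=5.0,
                                delta_phi=0.0, window=20.0,
                                n_realizations=20, seed=7)
        flat = table[table.epsilon == 0.0].iloc[0]
        osc = table[table.epsilon == 1.0].iloc[0]
        joint = math.hypot(flat["se"], osc["se"])
        assert osc["mean"] > flat["mean"] - 3 * joint


class TestMalleability:
    def test_constant_surface_is_zero(self):
        surf = SusceptibilitySurface(np.array([1.0, 2.0]), np.array([0.0, 1.0]),
                                     np.full((2, 2), 0.7), np.zeros((2, 2)))
        np.testing.assert_array_equal(malleability(surf), 0.0)

    def test_invariant_under_constant_offset(self, pair_vc23):
        phases = np.linspace(0, 2 * math.pi, 8, endpoint=False)
        surf = analytic_surface(pair_vc23, [2.0, 6.0, 20.0], phases)
        shifted = SusceptibilitySurface(surf.f_mod, surf.delta_phi,
                                        surf.mean + 5.0, surf.se)
        np.testing.assert_allclose(malleability(shifted), malleability(surf))

    def test_balanced_window_peaks_in_theta_band(self, pair_vc23):
        phases = np.linspace(0, 2 * math.pi, 16, endpoint=False)
        f_grid = np.arange(1.0, 81.0)
        mal = malleability(analytic_surface(pair_vc23, f_grid, phases))
        assert f_grid[int(np.argmax(mal))] in (6.0, 7.0)

    def test_single_phase_rejected(self, pair_vc23):
        surf = analytic_surface(pair_vc23, [2.0, 6.0], [0.0])
        with pytest.raises(ValueError):
            malleability(surf)


class TestSurfaceIO:
    def test_csv_round_trip(self, pair_vc23, tmp_path):
        phases = np.linspace(-np.pi, np.pi, 4, endpoint=False)
        surf = analytic_surface(pair_vc23, [1.0, 6.0, 30.0], phases)
        path = tmp_path / "surface.csv"
        surf.to_csv(path)
        again = SusceptibilitySurface.from_csv(path)
        np.testing.assert_allclose(again.f_mod, surf.f_mod)
        np.testing.assert_allclose(again.mean, surf.mean, rtol=1e-15)
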