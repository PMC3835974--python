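# synplast

Dynamical models of spike-timing-dependent plasticity (STDP) for
computational neuroscientists: simulate how a synapse changes under complex
spike patterns, fit plasticity rules to induction experiments, and analyse
the susceptibility of synaptic change to theta-band firing-rate
oscillations.

## What it implements

**Contribution-dynamics (CD) model.** Pair-based STDP written as
differential Hebbian learning — each spike leaves an exponential trace
*y<sub>i</sub>* (decay τ<sub>i</sub>) and the weight moves as
*ẇ = c<sub>w</sub> y*<sub>pre</sub>(*q x*<sub>post</sub> −
*y*<sub>post</sub>/τ<sub>post</sub>) — extended with two mechanisms the
plain pair rule lacks:

* **Adaptation** *u<sub>i</sub>*: a multiplicative resource per synaptic
  side. A spike consumes the fraction *c<sub>i</sub>*
  (*u ← u(1 − c<sub>i</sub>)*), recovery towards 1 with
  τ<sup>rec</sup><sub>i</sub>; trace increments are scaled by
  *u<sub>i</sub>(t−0)*. This is the analogue of short-term depression and
  makes spikes in rapid sequences count less.
* **Conditional activation** *q(t)*: the LTP scale becomes a trace of
  postsynaptic activity gated by presynaptic context — at a postsynaptic
  spike *q* jumps by *c<sub>q</sub>* only if *y*<sub>pre</sub>(t−0) >
  ϑ<sub>q</sub>, and relaxes to *q*<sub>min</sub> with τ<sub>q</sub>.
  With *q*<sub>min</sub> = 1/(1 + τ<sub>post</sub>/τ<sub>pre</sub>) a lone
  pre-post pair changes nothing, while a pre-post-post triplet potentiates
  — the "priming" phenomenology of somatosensory-cortex experiments.

**Reference rules.** The balanced/biased pair rule (all-to-all exponential
STDP window) and the triplet rule (pair traces r₁/o₁ plus slower triplet
traces r₂/o₂, all-to-all or nearest-neighbor trace updates).

**Protocols and fitting.** Declarative builders for the classic induction
protocols (low-frequency pairs, "5–5" pair bursts, triplets, 1−n and n−1
burst pairings), EPSP-ratio bookkeeping (ratio = 1 + Δw for unit initial
weight), SEM-normalized error
*E = (1/N) Σ ((Δw<sup>exp</sup> − Δw<sup>model</sup>)/SEM)²*, and a
deterministic brute-force grid search with refinement, including ablated
(reduced-model) fits. Fitted parameter tables for the four classic datasets
(VC5, HC, SC23, VC23) ship as package fixtures; because the experimental
Δw/SEM values are not redistributable, fitting is validated by parameter
recovery on synthetic records generated from a known ground-truth model.

**Theta susceptibility.** Under independent Poisson firing with sinusoidally
modulated rates r<sub>pre/post</sub> = r<sub>base</sub>(1 + ε cos(ω t −
φ<sub>i</sub>)), the pair rule's period-averaged weight-change rate has a
closed form (steady-state first-order filter response of the traces). For
the balanced rule it is a band-pass in the modulation frequency with peak

  f_max = 1 / (2π √(τ_pre τ_post)) — 6.56 Hz for τ = 14/42 ms,

i.e. squarely in the theta band. Non-linear rules (CD, triplet) are
analysed by Monte-Carlo surfaces over (f_mod, Δφ), with component ablations
and oscillation-amplitude sweeps.

## Worked example

```python
from synplast import (load_params, multi_spike_protocol, one_to_n_pattern,
                      pair_protocol, realize, simulate_cd, epsp_ratio, f_max)

fx = load_params("SC23", "cd")          # fitted somatosensory-cortex set
pair = pair_protocol(+0.010, 60, 0.1)   # pre-post, +10 ms, 60x at 0.1 Hz
trip = multi_spike_protocol(one_to_n_pattern(2, 100.0, 0.010), 60, 0.1)

for name, proto in [("pre-post", pair), ("pre-post-post", trip)]:
    dw = simulate_cd(*realize(proto), fx.params).delta_w
    print(f"{name:14s} delta_w = {dw:.4f}  EPSP ratio = {epsp_ratio(dw):.4f}")
print(f"f_max(14 ms, 42 ms) = {f_max(0.014, 0.042):.2f} Hz")
```

prints

```
pre-post       delta_w = 0.0000  EPSP ratio = 1.0000
pre-post-post  delta_w = 0.8485  EPSP ratio = 1.8485
f_max(14 ms, 42 ms) = 6.56 Hz
```

The lone pair leaves the synapse unchanged (the relaxed activation level
exactly balances potentiation against depression), while adding one
postsynaptic spike 10 ms later potentiates strongly — the non-linearity the
CD model was built to capture. The last line is the modulation frequency a
balanced-STDP synapse is most susceptible to.

The same runs are available from the shell:

```sh
synplast simulate --model cd --dataset SC23 --protocol proto.json --out out.json
synplast susceptibility --model spstdp --params pair.json --analytic \
    --f-mod 1:80 --n-phases 16 --out surface.csv
synplast fit --model cd --records records.csv --protocols protocols.json --out fit.json
synplast window --tau-pre 0.014 --tau-post 0.042 --out window.csv
synplast fixtures export --out fixtures.json
```

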