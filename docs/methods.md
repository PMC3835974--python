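# Methods

## Models

### Pair-based STDP as differential Hebbian learning

Spike trains are delta combs x_i(t) = Σ_k δ(t − t_i^k), i ∈ {pre, post}.
Each spike increments an exponential trace,

    dy_i/dt = −y_i/τ_i + x_i,

and the weight follows

    dw/dt = c_w · y_pre · (q · x_post − y_post/τ_post).

Summed over a pattern this is exactly the all-to-all exponential STDP
window: for a single pair at Δt = t_post − t_pre,

    Δw = c_w (q − k) e^{−Δt/τ_pre}    (Δt ≥ 0),
    Δw = −c_w k e^{Δt/τ_post}         (Δt < 0),      k = 1/(1 + τ_post/τ_pre).

q = 1 is the balanced rule (equal LTP/LTD areas, both c_w·τ_pre·τ_post/
(τ_pre+τ_post)); q = k cancels potentiation for every pattern. Δt = 0 is
defined as the limit from above (the potentiation branch); coincident
pre/post spikes are resolved by the integrator's tie-break below.

### Contribution-dynamics (CD) model

Two additions. Per-side adaptation resources

    du_i/dt = (1 − u_i)/τ_i^rec − c_i u_i(t−0) x_i,

consumed multiplicatively at a spike (u ← u(1 − c_i), the exact solution of
the delta term) and feeding the trace increments, dy_i/dt = −y_i/τ_i +
u_i(t−0) x_i. And a conditional activation replacing the fixed LTP scale,

    dq/dt = (q_min − q)/τ_q + c_q Θ(y_pre − ϑ_q) x_post,

so recent presynaptic activity gates the upregulation of potentiation. The
weight rule reads all state just before a spike:

    dw/dt = c_w y_pre (q(t−0) u_post(t−0) x_post − y_post/τ_post).

A negative threshold ϑ_q means the gate is always open (y_pre ≥ 0); we
store that case as −inf and serialize it as JSON null. With q_min = k and a
relaxed synapse, a lone pre-post pair cancels identically: the potentiation
jump c_w·k·e^{−Δt/τ_pre} equals the depression-tail integral
c_w·e^{−Δt/τ_pre}·τ_pre/(τ_pre+τ_post). This identity holds to machine
precision in the event-driven integrator and is asserted in the tests.

### Triplet rule

Pair traces r1 (decay τ_plus) and o1 (τ_minus), triplet traces r2 (τ_x)
and o2 (τ_y). At a postsynaptic spike w += r1(t−0)(A2⁺ + A3⁺·o2(t−0)); at a
presynaptic spike w −= o1(t−0)(A2⁻ + A3⁻·r2(t−0)). Trace updates are +1
per spike (all-to-all) or a reset to 1 (nearest-neighbor). A triplet time
constant may be omitted only when its amplitude is zero. Whether
"nearest neighbor" should restrict pair interactions beyond the trace reset
is left undefined in the literature we follow; only the trace-reset
semantics is implemented.

## Integration

All between-spike dynamics are linear, so the event-driven integrator is
exact: traces decay as y·e^{−Δt/τ}, resources recover as 1−(1−u)e^{−Δt/τrec},
the activation as q_min+(q−q_min)e^{−Δt/τ_q}, and the continuous depression
term integrates in closed form over each inter-event interval,
∫ y_pre y_post dt = y_pre y_post τ_h (1 − e^{−Δt/τ_h}) with
1/τ_h = 1/τ_pre + 1/τ_post. By default the depression tail is carried to
infinity (the full weight change of a pattern); a finite `t_end` truncates
there, which windowed-rate estimates require.

Event ordering at a pre/post coincidence is fixed: read all state at t−0,
apply presynaptic updates, then postsynaptic updates using the t−0 reads.
Pre-before-post is an arbitrary but documented tie-break; it matters only
for exactly coincident spikes. Coincident same-side spikes are rejected as
degenerate input.

A forward-Euler integrator (default step 0.1 ms, configurable) provides an
independent cross-check; it subdivides each inter-event interval so spike
times are honoured exactly rather than snapped to a grid. The property
suite requires agreement with the exact integrator to 1e−3 relative at a
0.01 ms step over randomized patterns. The randomized battery uses
gate-open or unreachable thresholds: near-threshold grazes would flip the
discrete gate decision between integrators and measure discretization of a
Heaviside, not integration accuracy; gating is tested deterministically.

Initial conditions everywhere: relaxed synapse at t = 0 (y = 0, u = 1,
q = q_min, w = 0). Weights are in units of the pre-induction weight, so
EPSP ratio = 1 + Δw.

## Protocols

Timing convention: Δt = t_post − t_pre, positive when the presynaptic spike
leads. Burst protocols anchor the leading spike of each pair, so "5 pairs
at 50 ms intervals" is a 20 Hz within-burst pairing rate. The repetition
count of the hippocampal triplet experiments is not published (only the
1 Hz rate); we default to 60 repetitions, matching the somatosensory
protocols, and make it configurable. Low-frequency pair protocols are
assumed to use 50 repetitions for both orderings.

## Fitting

The error is the mean squared SEM-normalized residual over records
(Gaussian log-likelihood up to constants, with published SEMs as weights).
Minimization is a deterministic brute-force scan: 8 points per free
dimension by default, geometric spacing for time constants and the weight
scale c_w (its box spans two decades), linear for fractions, amplitudes
and thresholds; then two refinement passes re-gridding the ±1-cell
neighbourhood of the incumbent at 4× resolution. The refined axis always
contains the incumbent coordinate, so a noiseless optimum on the initial
grid is retained exactly. Fixed-parameter rules follow the source
experiments: window constants fixed per dataset (14/42 ms, or 17/34 ms for
the hippocampal set), q_min set by the outcome of the low-frequency pair
experiment (q_min = k if "no change", else 1), and presynaptic adaptation
clamped off where every pattern holds a single presynaptic spike.

The four datasets' measured Δw/SEM values are not redistributable, so the
published fitting errors stored with the fixtures are reference metadata
only. Fitting correctness is accepted through synthetic recovery: noiseless
records generated at grid points are recovered exactly (E = 0), and with
noise at the SEM scale the argmin lands within one grid cell of the truth
in ≥ 90% of 50 seeded replicates. The recovery study frees (c_q, c_w) with
the remaining parameters fixed at the somatosensory-cortex values, uses six
pair/1−n protocols at 60 repetitions per pattern (the published repetition
schedule) and sem = noise_sd = 0.05, a typical published SEM magnitude.
Note one inconsistency preserved verbatim: the published SC23 triplet fit
lies outside the declared triplet search box (τ_x = 7.7 s > 5 s,
A3⁺ = 0.211 > 0.1); the fixture keeps the printed values and the
consistency test asserts the exception explicitly.

## Oscillatory susceptibility

Rates: r_pre = r_base(1 + ε cos ωt), r_post = r_base(1 + ε cos(ωt − Δφ)),
Δφ > 0 meaning pre leads. Defaults: ε = 1 (the modulation depth is
otherwise unconstrained), burn-in 2 s, averaging window 98 s, bin width
0.1 ms, integer modulation frequencies so the window is a whole number of
periods. The test suite runs scaled-down windows (20 s) and realization
counts; the acceptance checks state their sizes explicitly.

Spike generation is binned Bernoulli: p(spike in bin) = r(t_center)·dt, at
most one spike per bin, the spike placed at the bin centre. This mirrors
the discrete-time construction the models assume rather than thinning; the
discretization bias of the mean drift is O(dt²) and far below Monte-Carlo
error at the defaults. Pre and post processes are independent — spike-spike
correlations from synaptic transmission are deliberately zero.

For the linear pair rule the mean traces obey d⟨y_i⟩/dt = −⟨y_i⟩/τ_i +
r_i(t), whose steady state is the first-order filter response H_i(ω) =
τ_i/(1 + iωτ_i) applied to the sinusoid. Because the sides are independent,
the drift factorizes exactly and the period-averaged rate is

    rate(f, Δφ) = c_w r_base² [ (q−1)τ_pre
        + (ε²/2) Re( H_pre(ω) e^{iΔφ} (q − H̄_post(ω)/τ_post) ) ].

We derived this closed form ourselves and verified it two ways before use:
against adaptive-quadrature integration of the mean-field ODEs (agreement
~1e−10 relative) and against Monte-Carlo simulation (3-SE agreement across
an 8×8 grid at 100 realizations). For q = 1 the DC terms cancel and the
magnitude is |H_pre(ω)| · ωτ_post/√(1+ω²τ_post²): a band-pass with peak at
exactly f_max = 1/(2π√(τ_pre τ_post)) and first-order (20 dB/decade)
skirts on both sides. Two consequences worth stating explicitly: (i) the
susceptibility vanishes in both frequency limits, but only at the
first-order rate — at 10⁻³ Hz and 10⁴ Hz the phase spread is still ~3×10⁻⁴
and ~1.5×10⁻³ of the peak, and suppression to 10⁻⁶ of the peak requires
roughly f < 10⁻⁶ Hz or f > 10⁷ Hz; (ii) on an integer 1–80 Hz grid the
malleability (max−min over phase at fixed frequency) argmax for τ = 14/42 ms
falls at 7 Hz (the continuous peak is 6.56 Hz, and 7 Hz edges out 6 Hz by
~0.15%). For biased rules (q ≠ 1) the DC offset survives and the phase
spread no longer vanishes at low frequency — the band-pass degrades into a
low-pass, which the tests also assert.

Monte-Carlo surfaces use one named generator per cell, seeded from
(seed, i, j) via `SeedSequence`, so cells are reproducible independently
and partial grids resume exactly. The spSTDP Monte-Carlo route runs
through the CD integrator with adaptation and activation disabled — an
exact reduction that is itself under test — because windowed accrual
(weight change within [t', t'+NT]) needs the integrator, not the all-pairs
window sum.

The high-rate mean field for the adapted trace: under constant-rate Poisson
firing the resource equilibrium is ⟨u⟩ = 1/(1 + c τ_rec r), giving
⟨y⟩ = τ r/(1 + c τ_rec r) → τ/(c τ_rec) as r → ∞. With the VC23
adaptation values (τ_pre = 14 ms, c_pre = 0.7, τ_rec = 0.6 s) the limit is
0.033 — below the activation threshold 0.1, which is why sustained constant
presynaptic firing cannot open the activation gate while oscillating firing
can.

## What the synthetic data does and does not show

The synthetic-experiment generator draws records from a known model plus
i.i.d. Gaussian noise with a common SEM. Real induction datasets have
heteroscedastic SEMs, between-cell variability, finite trial counts and
possible systematic (non-Gaussian) deviations from any rule; passing the
recovery criteria therefore shows the estimator is correct and usable at
realistic noise scales, not that the CD model is identified by any
particular experimental design. Likewise the Poisson surface analysis
assumes independent sides; real pre/post pairs are coupled by transmission,
so measured susceptibilities would include correlation terms this analysis
deliberately excludes.

## Known limitations

- No weight bounds or homeostasis: the CD and triplet rules are unbounded,
  so Δw grows linearly with protocol repetitions.
- Calcium- and voltage-based plasticity models are out of scope.
- The brute-force search scales exponentially in the number of free
  parameters; the defaults are sized for ≤ 3 free dimensions. Use the
  fixed-parameter rules to keep searches tractable, as the original fits
  did.
- The event-driven integrator assumes exact spike times; patterns with
  astronomically close (but unequal) spikes are handled correctly but the
  closed-form interval integrals can lose relative precision below ~1e−15
  of the weight scale.
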