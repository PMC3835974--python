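"""The three plasticity rules and their integrators.

Pair-based STDP (differential Hebbian learning)
    Each spike leaves an exponential trace ``y_i`` on its side
    (``dy/dt = -y/tau_i + x_i``) and the weight moves as
    ``dw/dt = c_w * y_pre * (q*x_post - y_post/tau_post)``. Summed over a
    pattern this is exactly the all-to-all exponential STDP window.

Contribution-dynamics (CD) model
    Adds per-side adaptation resources ``u_i`` (a spike consumes the fraction
    ``c_i``, recovery constant ``tau_rec_i``), trace increments scaled by
    ``u_i(t-0)``, and a conditional activation ``q`` that replaces the fixed
    LTP scale: ``q`` jumps by ``c_q`` at a postsynaptic spike iff
    ``y_pre(t-0) > theta_q`` and relaxes to ``q_min`` with ``tau_q``. The
    weight rule reads all state at ``t-0``:
    ``dw/dt = c_w * y_pre * (q(t-0)*u_post(t-0)*x_post - y_post/tau_post)``.

Triplet rule
    Pair traces ``r1``/``o1`` plus slower triplet traces ``r2``/``o2``. At a
    postsynaptic spike ``w += r1(t-0)*(A2+ + A3+*o2(t-0))``; at a presynaptic
    spike ``w -= o1(t-0)*(A2- + A3-*r2(t-0))``. Traces either accumulate
    (+1 per spike, all-to-all) or reset to unity (nearest-neighbor).

All dynamics between spikes are linear, so the event-driven integrator
advances state with exact exponential solutions and accrues the continuous
depression term in closed form (product of two exponentials). A forward-Euler
integrator is provided for cross-validation; it subdivides inter-spike
intervals so spike times are honoured exactly.

Event ordering at a pre/post coincidence is fixed and documented: all state
is read at ``t-0`` first, then presynaptic updates are applied, then
postsynaptic updates (which use the ``t-0`` reads).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .params import CDParams, PairStdpParams, TripletParams
from .trains import SpikeTrain

__all__ = [
    "SimulationResult",
    "stdp_window",
    "simulate_spstdp",
    "simulate_cd",
    "simulate_triplet",
    "check_cd_reduces_to_spstdp",
]


@dataclass(frozen=True)
class SimulationResult:
    """Outcome of one protocol simulation.

    ``delta_w`` is the total accumulated weight change (dimensionless, for
    unit initial weight). ``trajectory`` optionally samples the state just
    after each spike event. ``w_samples`` holds the accumulated weight change
    at caller-supplied ``sample_times`` (used for windowed-rate estimates).
    """

    delta_w: float
    trajectory: Optional[pd.DataFrame] = None
    w_samples: Optional[np.ndarray] = None

    def __post_init__(self):
        if not math.isfinite(self.delta_w):
            raise ValueError("delta_w must be finite")
        if self.trajectory is not None:
            t = self.trajectory["t"].to_numpy()
            if np.any(np.diff(t) < 0):
                raise ValueError("trajectory timestamps must be non-decreasing")


# --------------------------------------------------------------------------
# pair-based STDP
# --------------------------------------------------------------------------

def stdp_window(params: PairStdpParams, delta_t):
    """Weight change of a single spike pair at ``delta_t = t_post - t_pre``.

    Positive ``delta_t`` (pre leads) hits the potentiation lobe
    ``c_w*(q - 1/(1+tau_post/tau_pre))*exp(-delta_t/tau_pre)``; negative the
    depression lobe ``-c_w/(1+tau_post/tau_pre)*exp(delta_t/tau_post)``.
    ``delta_t = 0`` takes the potentiation branch (the limit from above; a
    coincident pair is resolved pre-before-post by the integrators).
    Accepts scalars or arrays.
    """
    dt = np.asarray(delta_t, dtype=float)
    if not np.all(np.isfinite(dt)):
        raise ValueError("delta_t must be finite")
    k = 1.0 / (1.0 + params.tau_post / params.tau_pre)
    adt = np.abs(dt)  # each lobe decays with |dt|; avoids overflow in the unused branch
    ltp = (params.q - k) * np.exp(-adt / params.tau_pre)
    ltd = -k * np.exp(-adt / params.tau_post)
    out = params.c_w * np.where(dt >= 0, ltp, ltd)
    return float(out) if np.isscalar(delta_t) else out


def simulate_spstdp(pre: SpikeTrain, post: SpikeTrain,
                    params: PairStdpParams) -> SimulationResult:
    """All-to-all pair rule: sum ``stdp_window`` over every (pre, post) pair."""
    if len(pre) == 0 or len(post) == 0:
        return SimulationResult(0.0)
    dt = np.subtract.outer(post.times, pre.times)  # t_post - t_pre
    return SimulationResult(float(np.sum(stdp_window(params, dt))))


# --------------------------------------------------------------------------
# event stream helpers
# --------------------------------------------------------------------------

def _merge_events(pre: SpikeTrain, post: SpikeTrain):
    """Sorted unique event times with pre/post flags; coincidences share one event."""
    times = np.union1d(pre.times, post.times)
    is_pre = np.isin(times, pre.times)
    is_post = np.isin(times, post.times)
    return times, is_pre, is_post


def _prep_samples(sample_times) -> np.ndarray:
    s = np.asarray(sample_times, dtype=float) if sample_times is not None else np.empty(0)
    if np.any(np.diff(s) < 0):
        raise ValueError("sample_times must be non-decreasing")
    return s


# --------------------------------------------------------------------------
# CD model, event-driven (exact)
# --------------------------------------------------------------------------

def _cd_event_driven(pre, post, p: CDParams, t_end, sample_times, record):
    times, is_pre, is_post = _merge_events(pre, post)
    samples = _prep_samples(sample_times)
    tau_h = 1.0 / (1.0 / p.tau_pre + 1.0 / p.tau_post)  # decay of y_pre*y_post
    ltd_scale = p.c_w * tau_h / p.tau_post

    n = times.size
    if n:
        gaps = np.diff(np.concatenate(([0.0], times)))
        e_pre = np.exp(-gaps / p.tau_pre)
        e_post = np.exp(-gaps / p.tau_post)
        e_rpre = np.exp(-gaps / p.tau_rec_pre)
        e_rpost = np.exp(-gaps / p.tau_rec_post)
        e_q = np.exp(-gaps / p.tau_q)
        e_h = np.exp(-gaps / tau_h)

    y_pre = y_post = 0.0
    u_pre = u_post = 1.0
    q = p.q_min
    w = 0.0
    t = 0.0
    si = 0
    w_samples = np.empty(samples.size)
    traj = [] if record else None
    if record:
        traj.append((0.0, y_pre, y_post, u_pre, u_post, q, w))

    def _emit_samples(upto, decay_from_t):
        # fill samples in (t, upto] using state frozen at time decay_from_t
        nonlocal si
        while si < samples.size and samples[si] <= upto:
            dt_s = samples[si] - decay_from_t
            w_samples[si] = w - ltd_scale * y_pre * y_post * (1.0 - math.exp(-dt_s / tau_h))
            si += 1

    for i in range(n):
        te = times[i]
        if t_end is not None and te > t_end:
            break
        if samples.size:
            _emit_samples(te, t)  # samples at exactly te report the t-0 weight
        # exact advance over the gap
        w -= ltd_scale * y_pre * y_post * (1.0 - e_h[i])
        y_pre *= e_pre[i]
        y_post *= e_post[i]
        u_pre = 1.0 - (1.0 - u_pre) * e_rpre[i]
        u_post = 1.0 - (1.0 - u_post) * e_rpost[i]
        q = p.q_min + (q - p.q_min) * e_q[i]
        t = te
        # t-0 reads
        y_pre0, u_pre0, u_post0, q0 = y_pre, u_pre, u_post, q
        if is_pre[i]:
            y_pre = y_pre0 + u_pre0
            u_pre = u_pre0 * (1.0 - p.c_pre)
        if is_post[i]:
            w += p.c_w * y_pre0 * q0 * u_post0
            if p.gate_always_open or y_pre0 > p.theta_q:
                q = q + p.c_q
            y_post = y_post + u_post0
            u_post = u_post0 * (1.0 - p.c_post)
        if record:
            traj.append((t, y_pre, y_post, u_pre, u_post, q, w))

    if t_end is None:
        if samples.size:
            _emit_samples(samples[-1], t)
        # flush the depression tail to infinity
        w -= ltd_scale * y_pre * y_post
    else:
        if samples.size:
            _emit_samples(t_end, t)
        w -= ltd_scale * y_pre * y_post * (1.0 - math.exp(-(t_end - t) / tau_h))
    if si < samples.size:
        raise ValueError("sample_times extend beyond the simulated interval")

    df = None
    if record:
        df = pd.DataFrame(traj, columns=["t", "y_pre", "y_post", "u_pre", "u_post", "q", "w"])
    return SimulationResult(float(w), trajectory=df,
                            w_samples=w_samples if samples.size else None)


# --------------------------------------------------------------------------
# CD model, forward Euler (cross-validation)
# --------------------------------------------------------------------------

def _cd_euler(pre, post, p: CDParams, dt, t_end):
    if dt <= 0:
        raise ValueError("euler integrator requires dt > 0")
    times, is_pre, is_post = _merge_events(pre, post)
    if t_end is None:
        # integrate until the depression tail is negligible
        t_end = (times[-1] if times.size else 0.0) + 20.0 * max(p.tau_pre, p.tau_post)

    y_pre = y_post = 0.0
    u_pre = u_post = 1.0
    q = p.q_min
    w = 0.0
    t = 0.0

    def _advance(h_total):
        nonlocal y_pre, y_post, u_pre, u_post, q, w, t
        nsteps = max(1, math.ceil(h_total / dt))
        h = h_total / nsteps
        for _ in range(nsteps):
            w += -p.c_w * y_pre * y_post / p.tau_post * h
            y_pre += -y_pre / p.tau_pre * h
            y_post += -y_post / p.tau_post * h
            u_pre += (1.0 - u_pre) / p.tau_rec_pre * h
            u_post += (1.0 - u_post) / p.tau_rec_post * h
            q += (p.q_min - q) / p.tau_q * h
        t += h_total

    for i in range(times.size):
        te = times[i]
        if te > t_end:
            break
        if te > t:
            _advance(te - t)
        y_pre0, u_pre0, u_post0, q0 = y_pre, u_pre, u_post, q
        if is_pre[i]:
            y_pre = y_pre0 + u_pre0
            u_pre = u_pre0 * (1.0 - p.c_pre)
        if is_post[i]:
            w += p.c_w * y_pre0 * q0 * u_post0
            if p.gate_always_open or y_pre0 > p.theta_q:
                q = q + p.c_q
            y_post = y_post + u_post0
            u_post = u_post0 * (1.0 - p.c_post)
    if t_end > t:
        _advance(t_end - t)
    return SimulationResult(float(w))


def simulate_cd(pre: SpikeTrain, post: SpikeTrain, params: CDParams,
                integrator: str = "event_driven", dt: float = 1e-4,
                t_end: Optional[float] = None, sample_times=None,
                record: bool = False) -> SimulationResult:
    """Simulate the CD model on a pair of spike trains.

    The synapse starts relaxed (``y = 0``, ``u = 1``, ``q = q_min``) at
    ``t = 0``. With ``t_end=None`` the depression integral is carried to
    infinity (the full weight change of the pattern); a finite ``t_end``
    truncates there, which is what windowed-rate estimates need.

    Parameters
    ----------
    integrator : {"event_driven", "euler"}
        ``event_driven`` solves the piecewise-linear dynamics exactly;
        ``euler`` is a forward-Euler cross-check with step ``dt`` (default
        0.1 ms) whose substeps honour spike times exactly.
    sample_times : array-like, optional
        Times at which to report the accumulated weight change
        (event-driven only).
    record : bool
        Store the post-update state at every spike event (event-driven only).
    """
    if integrator == "event_driven":
        return _cd_event_driven(pre, post, params, t_end, sample_times, record)
    if integrator == "euler":
        if sample_times is not None or record:
            raise ValueError("sampling/recording is supported by the event-driven integrator")
        return _cd_euler(pre, post, params, dt, t_end)
    raise ValueError(f"unknown integrator {integrator!r}")


# --------------------------------------------------------------------------
# Triplet rule
# --------------------------------------------------------------------------

def simulate_triplet(pre: SpikeTrain, post: SpikeTrain, params: TripletParams,
                     sample_times=None, record: bool = False) -> SimulationResult:
    """Event-driven simulation of the triplet rule (pure jump process)."""
    p = params
    times, is_pre, is_post = _merge_events(pre, post)
    samples = _prep_samples(sample_times)
    nn = p.mode == "nearest_neighbor"

    r1 = r2 = o1 = o2 = 0.0
    w = 0.0
    t = 0.0
    si = 0
    w_samples = np.empty(samples.size)
    traj = [] if record else None
    if record:
        traj.append((0.0, r1, r2, o1, o2, w))

    for i in range(times.size):
        te = times[i]
        while si < samples.size and samples[si] < te:
            w_samples[si] = w
            si += 1
        h = te - t
        r1 *= math.exp(-h / p.tau_plus)
        o1 *= math.exp(-h / p.tau_minus)
        if p.tau_x is not None:
            r2 *= math.exp(-h / p.tau_x)
        if p.tau_y is not None:
            o2 *= math.exp(-h / p.tau_y)
        t = te
        r1_0, r2_0, o1_0, o2_0 = r1, r2, o1, o2
        if is_pre[i]:
            w -= o1_0 * (p.A2_minus + p.A3_minus * r2_0)
            r1 = 1.0 if nn else r1_0 + 1.0
            if p.tau_x is not None:
                r2 = 1.0 if nn else r2_0 + 1.0
        if is_post[i]:
            w += r1_0 * (p.A2_plus + p.A3_plus * o2_0)
            o1 = 1.0 if nn else o1_0 + 1.0
            if p.tau_y is not None:
                o2 = 1.0 if nn else o2_0 + 1.0
        if record:
            traj.append((t, r1, r2, o1, o2, w))

    while si < samples.size:
        w_samples[si] = w
        si += 1
    df = None
    if record:
        df = pd.DataFrame(traj, columns=["t", "r1", "r2", "o1", "o2", "w"])
    return SimulationResult(float(w), trajectory=df,
                            w_samples=w_samples if samples.size else None)


# --------------------------------------------------------------------------
# consistency bridge
# --------------------------------------------------------------------------

def check_cd_reduces_to_spstdp(pair_params: PairStdpParams,
                               patterns: Sequence[tuple[SpikeTrain, SpikeTrain]],
                               rtol: float = 1e-10) -> bool:
    """True iff the CD model with adaptation/activation disabled matches the
    all-to-all pair rule on every supplied (pre, post) pattern."""
    cd = CDParams.from_pair(pair_params)
    for pre, post in patterns:
        a = simulate_cd(pre, post, cd).delta_w
        b = simulate_spstdp(pre, post, pair_params).delta_w
        if abs(a - b) > rtol * max(abs(a), abs(b), pair_params.c_w * 1e-3):
            return False
    return True
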