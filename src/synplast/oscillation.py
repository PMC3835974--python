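"""Susceptibility of synaptic plasticity to oscillating firing rates.

Pre- and postsynaptic neurons fire as independent inhomogeneous Poisson
processes whose rates are sinusoidally modulated,

    r_pre(t)  = r_base * (1 + eps * cos(w_mod t)),
    r_post(t) = r_base * (1 + eps * cos(w_mod t - dphi)),

with ``dphi > 0`` meaning the presynaptic population leads. The quantity of
interest is the time-averaged rate of weight change after transients, as a
function of modulation frequency ``f_mod`` and phase shift ``dphi``
(the susceptibility surface).

For the linear pair rule the surface has a closed form: the mean traces are
the steady-state response of a first-order filter, ``H_i(w) =
tau_i / (1 + i w tau_i)``, and inserting them into the mean drift gives

    rate = c_w r_base^2 [ (q-1) tau_pre
           + (eps^2/2) Re( H_pre(w) e^{i dphi} (q - conj(H_post(w))/tau_post) ) ].

For ``q = 1`` this is a band-pass filter of the modulation frequency with
peak at ``f_max = 1/(2 pi sqrt(tau_pre tau_post))`` and first-order
(20 dB/decade) skirts on both sides. The closed form is verified in the
test suite against numerical quadrature of the mean-field equations and
against Monte-Carlo simulation.

Non-linear rules (CD, triplet) have no tractable mean field; their surfaces
are Monte-Carlo estimates over independent realizations of binned-Bernoulli
Poisson spike trains fed through the exact event-driven integrators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import simulate_cd, simulate_triplet
from .params import CDParams, PairStdpParams, with_updates
from .trains import SpikeTrain

__all__ = [
    "OscillationSpec", "SusceptibilitySurface",
    "rate_profile", "sample_poisson_train",
    "spstdp_susceptibility_analytic", "analytic_surface", "f_max",
    "mc_susceptibility_surface", "ablate_cd", "mean_field_y_infinity",
    "amplitude_sweep", "malleability",
]


@dataclass(frozen=True)
class OscillationSpec:
    """Oscillatory firing-rate specification.

    ``r_base`` in Hz, ``epsilon`` in [0, 1], ``f_mod`` in Hz, ``delta_phi``
    in radians (positive = pre leads), ``duration``/``burn_in`` in seconds,
    ``dt`` the Bernoulli bin width in seconds.
    """

    r_base: float
    f_mod: float
    delta_phi: float = 0.0
    epsilon: float = 1.0
    duration: float = 100.0
    burn_in: float = 2.0
    dt: float = 1e-4

    def __post_init__(self):
        if not 0 <= self.epsilon <= 1:
            raise ValueError("epsilon must be in [0, 1]")
        if self.f_mod <= 0:
            raise ValueError("f_mod must be > 0")
        if self.r_base < 0:
            raise ValueError("r_base must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.burn_in >= self.duration:
            raise ValueError("burn_in must be < duration")
        if self.r_base * (1 + self.epsilon) * self.dt >= 1:
            raise ValueError("r_base*(1+epsilon)*dt must be < 1 (Bernoulli bin)")


def rate_profile(spec: OscillationSpec, side: str, t):
    """Instantaneous firing rate (Hz) of one side at time(s) ``t``."""
    t = np.asarray(t, dtype=float)
    w = 2 * math.pi * spec.f_mod
    phi = 0.0 if side == "pre" else spec.delta_phi
    out = spec.r_base * (1 + spec.epsilon * np.cos(w * t - phi))
    return float(out) if out.ndim == 0 else out


def sample_poisson_train(spec: OscillationSpec, side: str, seed) -> SpikeTrain:
    """Inhomogeneous Poisson train by binned Bernoulli sampling.

    Bins of width ``dt`` tile [0, duration); the spike probability in a bin
    is the rate at the bin centre times ``dt`` (at most one spike per bin),
    and a spike is placed at the bin centre. ``seed`` may be an int or a
    ``numpy.random.Generator``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(spec.duration / spec.dt))
    centers = (np.arange(n) + 0.5) * spec.dt
    p = rate_profile(spec, side, centers) * spec.dt
    if np.any(p >= 1):
        raise ValueError("bin spike probability >= 1; decrease dt")
    hits = rng.random(n) < p
    return SpikeTrain(centers[hits], side)


# --------------------------------------------------------------- closed form

def f_max(tau_pre: float, tau_post: float) -> float:
    """Modulation frequency of maximal susceptibility, 1/(2*pi*sqrt(tau_pre*tau_post))."""
    if tau_pre <= 0 or tau_post <= 0:
        raise ValueError("time constants must be > 0")
    return 1.0 / (2 * math.pi * math.sqrt(tau_pre * tau_post))


def spstdp_susceptibility_analytic(params: PairStdpParams,
                                   spec: OscillationSpec) -> float:
    """Closed-form period-averaged weight-change rate for the pair rule.

    Steady-state mean traces are first-order filter responses to the
    sinusoidal rates; the DC parts contribute ``(q-1)*tau_pre*r_base^2`` and
    the oscillatory parts the phase-dependent band-pass term. Units: weight
    change per second (scales with ``r_base**2``; use ``r_base = 1`` for the
    rate-free normalization).
    """
    w = 2 * math.pi * spec.f_mod
    h_pre = params.tau_pre / (1 + 1j * w * params.tau_pre)
    h_post_conj = params.tau_post / (1 - 1j * w * params.tau_post)
    dc = (params.q - 1.0) * params.tau_pre
    osc = 0.5 * spec.epsilon ** 2 * np.real(
        h_pre * np.exp(1j * spec.delta_phi) * (params.q - h_post_conj / params.tau_post))
    return float(params.c_w * spec.r_base ** 2 * (dc + osc))


# ------------------------------------------------------------------ surfaces

@dataclass(frozen=True)
class SusceptibilitySurface:
    """Grid of time-averaged weight-change rates over (f_mod, delta_phi).

    ``mean`` and ``se`` are (len(f_mod), len(delta_phi)) arrays in 1/s;
    ``se`` is zero for analytic surfaces. ``metadata`` records how the
    surface was produced (model kind, params, sampling settings, seed).
    """

    f_mod: np.ndarray
    delta_phi: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        f = np.asarray(self.f_mod, dtype=float)
        p = np.asarray(self.delta_phi, dtype=float)
        if np.any(np.diff(f) <= 0) or np.any(np.diff(p) <= 0):
            raise ValueError("grids must be strictly increasing")
        m = np.asarray(self.mean, dtype=float)
        s = np.asarray(self.se, dtype=float)
        if m.shape != (f.size, p.size) or s.shape != m.shape:
            raise ValueError("mean/se shape must be (len(f_mod), len(delta_phi))")
        if np.any(s[np.isfinite(s)] < 0):
            raise ValueError("standard errors must be >= 0")
        object.__setattr__(self, "f_mod", f)
        object.__setattr__(self, "delta_phi", p)
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "se", s)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        n = self.metadata.get("n_realizations", 0)
        for i, f in enumerate(self.f_mod):
            for j, ph in enumerate(self.delta_phi):
                rows.append((f, ph, self.mean[i, j], self.se[i, j], n))
        return pd.DataFrame(rows, columns=["f_mod", "delta_phi", "mean", "se", "n"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, metadata: Optional[dict] = None) -> "SusceptibilitySurface":
        df = pd.read_csv(path, float_precision="round_trip")
        f = np.unique(df["f_mod"])
        p = np.unique(df["delta_phi"])
        mean = np.full((f.size, p.size), np.nan)
        se = np.full((f.size, p.size), np.nan)
        fi = {v: i for i, v in enumerate(f)}
        pj = {v: j for j, v in enumerate(p)}
        for _, row in df.iterrows():
            mean[fi[row["f_mod"]], pj[row["delta_phi"]]] = row["mean"]
            se[fi[row["f_mod"]], pj[row["delta_phi"]]] = row["se"]
        return cls(f, p, mean, se, metadata or {})


def analytic_surface(params: PairStdpParams, f_mod: Sequence[float],
                     delta_phi: Sequence[float], r_base: float = 1.0,
                     epsilon: float = 1.0) -> SusceptibilitySurface:
    """Evaluate the pair-rule closed form on a (f_mod, delta_phi) grid."""
    f_mod = np.asarray(f_mod, dtype=float)
    delta_phi = np.asarray(delta_phi, dtype=float)
    mean = np.empty((f_mod.size, delta_phi.size))
    for i, f in enumerate(f_mod):
        for j, ph in enumerate(delta_phi):
            spec = OscillationSpec(r_base=r_base, f_mod=f, delta_phi=ph,
                                   epsilon=epsilon, duration=1.0, burn_in=0.0)
            mean[i, j] = spstdp_susceptibility_analytic(params, spec)
    return SusceptibilitySurface(f_mod, delta_phi, mean, np.zeros_like(mean),
                                 {"model": "spstdp", "analytic": True,
                                  "r_base": r_base, "epsilon": epsilon})


# ------------------------------------------------------------- Monte Carlo

def _windowed_rate(model_kind: str, params, pre: SpikeTrain, post: SpikeTrain,
                   burn_in: float, duration: float) -> float:
    samples = [burn_in, duration]
    if model_kind == "triplet":
        res = simulate_triplet(pre, post, params, sample_times=samples)
    else:
        res = simulate_cd(pre, post, params, t_end=duration, sample_times=samples)
    w0, w1 = res.w_samples
    return (w1 - w0) / (duration - burn_in)


def _as_sim_params(model_kind: str, params):
    if model_kind == "spstdp":
        return "cd", CDParams.from_pair(params)
    return model_kind, params


def mc_susceptibility_surface(model_kind: str, params,
                              f_mod: Sequence[float],
                              delta_phi: Sequence[float], *,
                              r_base: float, epsilon: float = 1.0,
                              window: float = 98.0, burn_in: float = 2.0,
                              dt: float = 1e-4, n_realizations: int = 100,
                              seed: int = 0,
                              resume_from: Optional[SusceptibilitySurface] = None
                              ) -> SusceptibilitySurface:
    """Monte-Carlo susceptibility surface for any of the three rules.

    Per grid cell, ``n_realizations`` independent (pre, post) Poisson train
    pairs are simulated and the weight change accrued over
    ``[burn_in, burn_in + window]`` divided by the window length is averaged;
    the standard error is across realizations. Integer ``f_mod`` values keep
    the window a whole number of periods. Each cell draws from its own
    substream seeded by (seed, i, j), so partial grids resume reproducibly:
    cells already finite in ``resume_from`` are copied, only missing cells
    are computed.
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    if burn_in >= burn_in + window or window <= 0:
        raise ValueError("window must be > 0")
    f_mod = np.asarray(f_mod, dtype=float)
    delta_phi = np.asarray(delta_phi, dtype=float)
    sim_kind, sim_params = _as_sim_params(model_kind, params)
    duration = burn_in + window

    mean = np.full((f_mod.size, delta_phi.size), np.nan)
    se = np.full_like(mean, np.nan)
    if resume_from is not None:
        if (resume_from.f_mod.size == f_mod.size
                and np.allclose(resume_from.f_mod, f_mod)
                and resume_from.delta_phi.size == delta_phi.size
                and np.allclose(resume_from.delta_phi, delta_phi)):
            mean[:] = resume_from.mean
            se[:] = resume_from.se
        else:
            raise ValueError("resume_from grids do not match")

    n_bins = int(round(duration / dt))
    centers = (np.arange(n_bins) + 0.5) * dt
    for i, f in enumerate(f_mod):
        w = 2 * math.pi * f
        p_pre = r_base * (1 + epsilon * np.cos(w * centers)) * dt
        if np.any(p_pre >= 1):
            raise ValueError("bin spike probability >= 1; decrease dt")
        for j, ph in enumerate(delta_phi):
            if np.isfinite(mean[i, j]) and np.isfinite(se[i, j]):
                continue
            p_post = r_base * (1 + epsilon * np.cos(w * centers - ph)) * dt
            rng = np.random.default_rng(np.random.SeedSequence([seed, i, j]))
            rates = np.empty(n_realizations)
            for k in range(n_realizations):
                pre = SpikeTrain(centers[rng.random(n_bins) < p_pre], "pre")
                post = SpikeTrain(centers[rng.random(n_bins) < p_post], "post")
                rates[k] = _windowed_rate(sim_kind, sim_params, pre, post,
                                          burn_in, duration)
            mean[i, j] = rates.mean()
            se[i, j] = rates.std(ddof=1) / math.sqrt(n_realizations) \
                if n_realizations > 1 else 0.0

    meta = {"model": model_kind, "r_base": r_base, "epsilon": epsilon,
            "window": window, "burn_in": burn_in, "dt": dt,
            "n_realizations": n_realizations, "seed": seed}
    return SusceptibilitySurface(f_mod, delta_phi, mean, se, meta)


# -------------------------------------------------------------- CD analysis

def ablate_cd(params: CDParams, component: str) -> CDParams:
    """Remove one CD-model component.

    ``pre_adaptation``/``post_adaptation`` set the respective consumption
    fraction to zero (u stays at 1); ``activation`` sets ``c_q = 0``
    (q stays at q_min).
    """
    if component == "pre_adaptation":
        return with_updates(params, c_pre=0.0)
    if component == "post_adaptation":
        return with_updates(params, c_post=0.0)
    if component == "activation":
        return with_updates(params, c_q=0.0)
    raise ValueError(f"unknown component {component!r}")


def mean_field_y_infinity(tau: float, c: float, tau_rec: float, rate) -> float:
    """Equilibrium mean spike trace under constant-rate Poisson firing.

    Each spike increments the trace by the adapted resource, whose mean
    equilibrium is 1/(1 + c*tau_rec*r); the mean trace is then
    ``tau*r/(1 + c*tau_rec*r)``. ``rate=inf`` gives the high-rate limit
    ``tau/(c*tau_rec)`` (requires c > 0).
    """
    if tau <= 0 or tau_rec <= 0:
        raise ValueError("time constants must be > 0")
    if math.isinf(rate):
        if not 0 < c <= 1:
            raise ValueError("the infinite-rate limit requires 0 < c <= 1")
        return tau / (c * tau_rec)
    if rate < 0:
        raise ValueError("rate must be >= 0")
    return tau * rate / (1.0 + c * tau_rec * rate)


def amplitude_sweep(model_kind: str, params, r_base_grid: Sequence[float],
                    epsilon_grid: Sequence[float], *, f_mod: float = 5.0,
                    delta_phi: float = 0.0, window: float = 98.0,
                    burn_in: float = 2.0, dt: float = 1e-4,
                    n_realizations: int = 100, seed: int = 0) -> pd.DataFrame:
    """Mean weight-change rate per (r_base, epsilon) cell at fixed f_mod, dphi.

    Same averaging contract as :func:`mc_susceptibility_surface`; returns a
    long-format DataFrame (r_base, epsilon, mean, se, n).
    """
    sim_kind, sim_params = _as_sim_params(model_kind, params)
    duration = burn_in + window
    n_bins = int(round(duration / dt))
    centers = (np.arange(n_bins) + 0.5) * dt
    w = 2 * math.pi * f_mod
    rows = []
    for i, rb in enumerate(np.asarray(r_base_grid, dtype=float)):
        for j, eps in enumerate(np.asarray(epsilon_grid, dtype=float)):
            p_pre = rb * (1 + eps * np.cos(w * centers)) * dt
            p_post = rb * (1 + eps * np.cos(w * centers - delta_phi)) * dt
            if np.any(p_pre >= 1) or np.any(p_post >= 1):
                raise ValueError("bin spike probability >= 1; decrease dt")
            rng = np.random.default_rng(np.random.SeedSequence([seed, i, j]))
            rates = np.empty(n_realizations)
            for k in range(n_realizations):
                pre = SpikeTrain(centers[rng.random(n_bins) < p_pre], "pre")
                post = SpikeTrain(centers[rng.random(n_bins) < p_post], "post")
                rates[k] = _windowed_rate(sim_kind, sim_params, pre, post,
                                          burn_in, duration)
            se = rates.std(ddof=1) / math.sqrt(n_realizations) \
                if n_realizations > 1 else 0.0
            rows.append((rb, eps, rates.mean(), se, n_realizations))
    return pd.DataFrame(rows, columns=["r_base", "epsilon", "mean", "se", "n"])


def malleability(surface: SusceptibilitySurface) -> np.ndarray:
    """Per-f_mod spread of the surface: max - min across the phase axis."""
    if surface.delta_phi.size < 2:
        raise ValueError("need at least two phase points")
    return surface.mean.max(axis=1) - surface.mean.min(axis=1)
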