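"""Induction protocols: declarative spike patterns and their realization.

A protocol is a spike *pattern* (relative times, sides) repeated a number of
times, either at a fixed repetition interval or organized into bursts of
spike pairs. Realization expands it deterministically into absolute (pre,
post) spike trains starting at t = 0 with the synapse at rest.

Timing convention throughout: ``delta_t = t_post - t_pre``; positive means
the presynaptic spike leads. Burst timing anchors the *leading* spike of
each pair, so "5 pairs at 50 ms intervals" places the leading spikes 50 ms
apart (a 20 Hz within-burst pairing rate).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .trains import SIDES, SpikeTrain

__all__ = [
    "SpikePattern", "InductionProtocol",
    "pair_protocol", "burst_protocol", "multi_spike_protocol",
    "triplet_pattern", "one_to_n_pattern", "n_to_one_pattern",
    "realize", "epsp_ratio",
    "protocol_to_dict", "protocol_from_dict",
]


@dataclass(frozen=True)
class SpikePattern:
    """One pattern instance: a list of (relative time s, side) events."""

    events: Tuple[Tuple[float, str], ...]

    def __post_init__(self):
        ev = tuple((float(t), s) for t, s in self.events)
        if not ev:
            raise ValueError("pattern must contain at least one event")
        for t, s in ev:
            if not np.isfinite(t) or t < 0:
                raise ValueError("pattern times must be finite and >= 0")
            if s not in SIDES:
                raise ValueError(f"pattern side must be in {SIDES}, got {s!r}")
        if len(set(ev)) != len(ev):
            raise ValueError("duplicate (time, side) event in pattern")
        object.__setattr__(self, "events", tuple(sorted(ev)))

    @property
    def duration(self) -> float:
        return max(t for t, _ in self.events)


@dataclass(frozen=True)
class InductionProtocol:
    """A repeated spike pattern.

    Either ``repetition_interval`` is set (uniform repetition of ``pattern``
    ``n_repetitions`` times), or the protocol was built as a burst protocol,
    in which case ``pattern`` holds one full burst and ``repetition_interval``
    the inter-burst interval; ``burst_structure`` keeps the burst bookkeeping
    (pairs_per_burst, intra_pair_interval, n_bursts, inter_burst_interval).
    """

    pattern: SpikePattern
    n_repetitions: int
    repetition_interval: float
    burst_structure: Optional[Tuple[int, float, int, float]] = None

    def __post_init__(self):
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if self.repetition_interval <= 0:
            raise ValueError("repetition_interval must be > 0")
        if self.n_repetitions > 1 and self.pattern.duration >= self.repetition_interval:
            raise ValueError("pattern longer than the repetition interval")

    @property
    def total_duration(self) -> float:
        return (self.n_repetitions - 1) * self.repetition_interval + self.pattern.duration


# ------------------------------------------------------------------ builders

def _pair_events(delta_t: float) -> tuple[tuple[float, str], ...]:
    if delta_t >= 0:  # pre leads
        return ((0.0, "pre"), (delta_t, "post"))
    return ((0.0, "post"), (-delta_t, "pre"))


def pair_protocol(delta_t: float, n_reps: int, rep_rate: float) -> InductionProtocol:
    """Single pre/post pair separated by ``|delta_t|``, repeated at ``rep_rate`` Hz."""
    if rep_rate <= 0:
        raise ValueError("rep_rate must be > 0")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    interval = 1.0 / rep_rate
    if interval <= abs(delta_t):
        raise ValueError("repetition interval must exceed the pair separation")
    return InductionProtocol(SpikePattern(_pair_events(delta_t)), n_reps, interval)


def burst_protocol(delta_t: float, intra_pair_interval: float,
                   pairs_per_burst: int, n_bursts: int,
                   inter_burst_interval: float) -> InductionProtocol:
    """Bursts of spike pairs: leading spikes ``intra_pair_interval`` apart,
    bursts starting ``inter_burst_interval`` apart."""
    if pairs_per_burst < 1 or n_bursts < 1:
        raise ValueError("counts must be >= 1")
    if intra_pair_interval <= abs(delta_t):
        raise ValueError("intra-pair interval must exceed the pair separation")
    burst_len = (pairs_per_burst - 1) * intra_pair_interval + abs(delta_t)
    if n_bursts > 1 and burst_len >= inter_burst_interval:
        raise ValueError("consecutive bursts overlap")
    events = []
    for k in range(pairs_per_burst):
        for t, s in _pair_events(delta_t):
            events.append((k * intra_pair_interval + t, s))
    return InductionProtocol(
        SpikePattern(tuple(events)), n_bursts, inter_burst_interval,
        burst_structure=(pairs_per_burst, intra_pair_interval, n_bursts,
                         inter_burst_interval))


def multi_spike_protocol(pattern: SpikePattern, n_reps: int,
                         rep_rate: float) -> InductionProtocol:
    """General builder: any valid pattern repeated at ``rep_rate`` Hz."""
    if rep_rate <= 0:
        raise ValueError("rep_rate must be > 0")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    interval = 1.0 / rep_rate
    if n_reps > 1 and pattern.duration >= interval:
        raise ValueError("pattern longer than the repetition interval")
    return InductionProtocol(pattern, n_reps, interval)


def triplet_pattern(order: str, lag1: float, lag2: float) -> SpikePattern:
    """Spike triplet, e.g. ``order="post-pre-post"`` with lags in seconds."""
    sides = order.split("-")
    if len(sides) != 3 or any(s not in SIDES for s in sides):
        raise ValueError(f"order must be like 'pre-post-pre', got {order!r}")
    if lag1 <= 0 or lag2 <= 0:
        raise ValueError("lags must be > 0")
    times = (0.0, lag1, lag1 + lag2)
    return SpikePattern(tuple(zip(times, sides)))


def one_to_n_pattern(n_post: int, burst_freq: float, delta_t: float) -> SpikePattern:
    """One presynaptic spike followed after ``delta_t`` by ``n_post``
    postsynaptic spikes at ``burst_freq`` Hz."""
    if n_post < 1:
        raise ValueError("n_post must be >= 1")
    step = 1.0 / burst_freq
    events = [(0.0, "pre")] + [(delta_t + k * step, "post") for k in range(n_post)]
    return SpikePattern(tuple(events))


def n_to_one_pattern(n_pre: int, burst_freq: float, delta_t: float,
                     post_first: bool = False) -> SpikePattern:
    """``n_pre`` presynaptic spikes in a burst at ``burst_freq`` Hz paired
    with one postsynaptic spike, ``delta_t`` after the burst end (or
    ``delta_t`` before the burst start when ``post_first``)."""
    if n_pre < 1:
        raise ValueError("n_pre must be >= 1")
    step = 1.0 / burst_freq
    if post_first:
        events = [(0.0, "post")] + [(delta_t + k * step, "pre") for k in range(n_pre)]
    else:
        burst_end = (n_pre - 1) * step
        events = [(k * step, "pre") for k in range(n_pre)] + [(burst_end + delta_t, "post")]
    return SpikePattern(tuple(events))


# ----------------------------------------------------------------- realize

def realize(protocol: InductionProtocol) -> tuple[SpikeTrain, SpikeTrain]:
    """Expand a protocol into absolute (pre, post) spike trains from t = 0."""
    pre, post = [], []
    for k in range(protocol.n_repetitions):
        offset = k * protocol.repetition_interval
        for t, s in protocol.pattern.events:
            (pre if s == "pre" else post).append(offset + t)
    return (SpikeTrain(np.asarray(pre), "pre"),
            SpikeTrain(np.asarray(post), "post"))


def epsp_ratio(delta_w: float) -> float:
    """EPSP amplitude ratio after/before induction, for unit initial weight."""
    return 1.0 + delta_w


# ------------------------------------------------------------- serialization

def protocol_to_dict(protocol: InductionProtocol) -> dict:
    if protocol.burst_structure is not None:
        ppb, ipi, nb, ibi = protocol.burst_structure
        # recover delta_t from the first pair of the burst pattern
        ev = protocol.pattern.events
        pre0 = min(t for t, s in ev if s == "pre")
        post0 = min(t for t, s in ev if s == "post")
        return {"type": "burst", "delta_t": post0 - pre0,
                "intra_pair_interval": ipi, "pairs_per_burst": ppb,
                "n_bursts": nb, "inter_burst_interval": ibi}
    ev = protocol.pattern.events
    if len(ev) == 2 and {s for _, s in ev} == set(SIDES):
        pre0 = next(t for t, s in ev if s == "pre")
        post0 = next(t for t, s in ev if s == "post")
        return {"type": "pair", "delta_t": post0 - pre0,
                "n_reps": protocol.n_repetitions,
                "rep_rate": 1.0 / protocol.repetition_interval}
    return {"type": "multi",
            "events": [[t, s] for t, s in ev],
            "n_reps": protocol.n_repetitions,
            "rep_rate": 1.0 / protocol.repetition_interval}


def protocol_from_dict(d: dict) -> InductionProtocol:
    kind = d.get("type")
    if kind == "pair":
        return pair_protocol(d["delta_t"], d["n_reps"], d["rep_rate"])
    if kind == "burst":
        return burst_protocol(d["delta_t"], d["intra_pair_interval"],
                              d["pairs_per_burst"], d["n_bursts"],
                              d["inter_burst_interval"])
    if kind == "multi":
        pattern = SpikePattern(tuple((t, s) for t, s in d["events"]))
        return multi_spike_protocol(pattern, d["n_reps"], d["rep_rate"])
    raise ValueError(f"unknown protocol type {kind!r}")


def protocols_to_json(protocols: dict[str, InductionProtocol]) -> str:
    return json.dumps({k: protocol_to_dict(v) for k, v in protocols.items()}, indent=2)


def protocols_from_json(text: str) -> dict[str, InductionProtocol]:
    return {k: protocol_from_dict(v) for k, v in json.loads(text).items()}
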