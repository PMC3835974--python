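"""Parameter vectors of the three plasticity rules.

All time constants are in seconds. Dimensionless quantities (trace
amplitudes, consumption fractions, the activation threshold) carry no unit.

The activation gate of the contribution-dynamics (CD) rule compares the
presynaptic trace ``y_pre`` (which is always >= 0) against the threshold
``theta_q``; a *negative* threshold therefore means the gate is always open.
We store that case canonically as ``-inf`` and serialize it as JSON ``null``.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace
from typing import Optional

GATE_OPEN = -math.inf


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class PairStdpParams:
    """Pair-based STDP (differential Hebbian) parameters.

    ``q`` scales the potentiation lobe of the window; ``q = 1`` is the
    balanced rule (equal LTP/LTD areas), ``q = 1/(1 + tau_post/tau_pre)``
    cancels LTP for every spike pattern.
    """

    tau_pre: float
    tau_post: float
    q: float = 1.0
    c_w: float = 1.0

    def __post_init__(self):
        _require(self.tau_pre > 0 and self.tau_post > 0, "time constants must be > 0")
        _require(self.q >= 0, "q must be >= 0")
        _require(self.c_w > 0, "c_w must be > 0")

    @property
    def balance_q(self) -> float:
        """The q that exactly cancels LTP: 1/(1 + tau_post/tau_pre)."""
        return 1.0 / (1.0 + self.tau_post / self.tau_pre)


@dataclass(frozen=True)
class CDParams:
    """Contribution-dynamics model parameters.

    Adaptation: each spike on side *i* consumes a fraction ``c_i`` of the
    resource ``u_i`` (multiplicative update ``u <- u * (1 - c_i)``), which
    recovers towards 1 with ``tau_rec_i``. Activation: at a postsynaptic
    spike, ``q`` jumps by ``c_q`` iff ``y_pre(t-0) > theta_q``, and relaxes
    towards ``q_min`` with ``tau_q``.
    """

    tau_pre: float
    tau_post: float
    tau_rec_pre: float
    tau_rec_post: float
    c_pre: float
    c_post: float
    q_min: float
    tau_q: float
    c_q: float
    theta_q: float
    c_w: float

    def __post_init__(self):
        for name in ("tau_pre", "tau_post", "tau_rec_pre", "tau_rec_post", "tau_q"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")
        _require(0 <= self.c_pre <= 1, "c_pre must be in [0, 1]")
        _require(0 <= self.c_post <= 1, "c_post must be in [0, 1]")
        _require(self.c_q >= 0, "c_q must be >= 0")
        _require(self.q_min >= 0, "q_min must be >= 0")
        _require(self.c_w > 0, "c_w must be > 0")
        _require(not math.isnan(self.theta_q), "theta_q must not be NaN")

    @property
    def gate_always_open(self) -> bool:
        """True when the activation threshold is negative (y_pre >= 0 always passes)."""
        return self.theta_q < 0

    @classmethod
    def from_pair(cls, pair: PairStdpParams) -> "CDParams":
        """Reduction: adaptation and activation disabled, q pinned at ``pair.q``.

        With ``c_pre = c_post = 0`` and ``c_q = 0`` the CD equations collapse
        exactly onto the differential Hebbian pair rule.
        """
        return cls(
            tau_pre=pair.tau_pre, tau_post=pair.tau_post,
            tau_rec_pre=1.0, tau_rec_post=1.0, c_pre=0.0, c_post=0.0,
            q_min=pair.q, tau_q=1.0, c_q=0.0, theta_q=GATE_OPEN, c_w=pair.c_w,
        )


@dataclass(frozen=True)
class TripletParams:
    """Triplet-rule parameters (pair traces r1/o1, triplet traces r2/o2).

    ``r1`` decays with ``tau_plus``, ``r2`` with ``tau_x``, ``o1`` with
    ``tau_minus`` and ``o2`` with ``tau_y``. A triplet time constant may be
    omitted (``None``) only when the amplitude that reads the corresponding
    trace is zero (``tau_x`` pairs with ``A3_minus``, ``tau_y`` with
    ``A3_plus``). ``mode`` selects the trace update at a spike: ``all_to_all``
    adds one, ``nearest_neighbor`` resets the trace to one.
    """

    tau_plus: float
    tau_minus: float
    A2_plus: float
    A2_minus: float
    A3_plus: float
    A3_minus: float
    tau_x: Optional[float] = None
    tau_y: Optional[float] = None
    mode: str = "all_to_all"

    def __post_init__(self):
        _require(self.tau_plus > 0 and self.tau_minus > 0, "pair time constants must be > 0")
        _require(self.A2_plus >= 0 and self.A2_minus >= 0, "pair amplitudes must be >= 0")
        if self.tau_x is None:
            _require(self.A3_minus == 0, "tau_x may be omitted only when A3_minus = 0")
        else:
            _require(self.tau_x > 0, "tau_x must be > 0")
        if self.tau_y is None:
            _require(self.A3_plus == 0, "tau_y may be omitted only when A3_plus = 0")
        else:
            _require(self.tau_y > 0, "tau_y must be > 0")
        _require(self.mode in ("all_to_all", "nearest_neighbor"),
                 f"unknown mode {self.mode!r}")


_CLASSES = {"pair_stdp": PairStdpParams, "cd": CDParams, "triplet": TripletParams}
_KINDS = {v: k for k, v in _CLASSES.items()}


def params_to_dict(params) -> dict:
    """Serializable dict with a ``model`` discriminator; -inf -> null."""
    d = asdict(params)
    d = {k: (None if isinstance(v, float) and math.isinf(v) and v < 0 else v)
         for k, v in d.items()}
    d["model"] = _KINDS[type(params)]
    return d


def params_from_dict(d: dict):
    d = dict(d)
    kind = d.pop("model")
    d.pop("dataset", None)
    cls = _CLASSES[kind]
    if cls is CDParams and d.get("theta_q") is None:
        d["theta_q"] = GATE_OPEN
    return cls(**d)


def params_to_json(params) -> str:
    return json.dumps(params_to_dict(params), indent=2)


def params_from_json(text: str):
    return params_from_dict(json.loads(text))


def with_updates(params, **kwargs):
    """Return a copy of a parameter set with some fields replaced."""
    return replace(params, **kwargs)
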