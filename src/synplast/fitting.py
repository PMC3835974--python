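"""SEM-normalized error and brute-force grid-search fitting.

The fit quality of a parameter vector pi against N induction experiments is

    E(pi) = (1/N) * sum_i ((dw_i_exp - dw_i_model(pi)) / SEM_i)**2,

the mean squared residual in units of each experiment's standard error.
Minimization is a deterministic brute-force scan of a rectangular grid over
the free parameters (log spacing for time constants and the weight scale,
linear for fractions, amplitudes and thresholds), optionally followed by
refinement passes that re-grid at 4x resolution around the incumbent. The
refined grid always contains the incumbent point, so a noiseless optimum
that lies on the initial grid is never lost.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import simulate_cd, simulate_triplet
from .params import CDParams, TripletParams
from .protocols import InductionProtocol, protocols_from_json, realize

__all__ = [
    "ExperimentRecord", "ParameterBounds", "FitResult",
    "predict_delta_w", "model_error", "q_min_rule",
    "grid_search_fit", "ablated_fit", "read_records",
]

# parameters whose search axis is geometric rather than linear
_LOG_PARAMS = {"tau_rec_pre", "tau_rec_post", "tau_q", "c_w", "tau_x", "tau_y"}


@dataclass(frozen=True)
class ExperimentRecord:
    """One induction experiment: protocol, measured weight change, SEM."""

    protocol: InductionProtocol
    delta_w_exp: float
    sem: float

    def __post_init__(self):
        if not math.isfinite(self.delta_w_exp):
            raise ValueError("delta_w_exp must be finite")
        if not (self.sem > 0):
            raise ValueError("sem must be > 0")


@dataclass(frozen=True)
class ParameterBounds:
    """Search domain: per-parameter (min, max), fixed values, grid spec.

    ``spacing`` maps a parameter name to "log" or "linear"; unnamed
    parameters default to log for time constants and the weight scale,
    linear otherwise.
    """

    bounds: Dict[str, Tuple[float, float]]
    fixed: Dict[str, float] = field(default_factory=dict)
    n_points: int = 8
    spacing: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"bounds for {name!r}: min must be < max")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")

    @property
    def free_names(self) -> List[str]:
        return [n for n in self.bounds if n not in self.fixed]

    def axis(self, name: str, lo=None, hi=None, n=None) -> np.ndarray:
        b_lo, b_hi = self.bounds[name]
        lo = b_lo if lo is None else max(lo, b_lo)
        hi = b_hi if hi is None else min(hi, b_hi)
        n = self.n_points if n is None else n
        if self.spacing.get(name, "log" if name in _LOG_PARAMS else "linear") == "log":
            if lo <= 0:
                raise ValueError(f"log axis for {name!r} needs positive bounds")
            return np.geomspace(lo, hi, n)
        return np.linspace(lo, hi, n)


@dataclass(frozen=True)
class FitResult:
    best_params: dict
    error: float
    n_evaluations: int
    residuals: np.ndarray  # per-record (dw_exp - dw_model)/sem

    def __post_init__(self):
        if self.error < 0:
            raise ValueError("error must be >= 0")

    def to_json(self) -> str:
        return json.dumps({
            "best_params": self.best_params, "error": self.error,
            "n_evaluations": self.n_evaluations,
            "residuals": np.asarray(self.residuals).tolist(),
        }, indent=2, default=float)


# --------------------------------------------------------------- evaluation

def _make_params(model_kind: str, values: dict):
    if model_kind == "cd":
        return CDParams(**values)
    if model_kind == "triplet":
        return TripletParams(**values)
    raise ValueError(f"unknown model kind {model_kind!r}")


def predict_delta_w(model_kind: str, params, protocol: InductionProtocol) -> float:
    """Model-predicted weight change for one protocol (event-driven, exact)."""
    pre, post = realize(protocol)
    if model_kind == "cd":
        return simulate_cd(pre, post, params).delta_w
    if model_kind == "triplet":
        return simulate_triplet(pre, post, params).delta_w
    raise ValueError(f"unknown model kind {model_kind!r}")


def model_error(records: Sequence[ExperimentRecord], model_kind: str,
                params) -> float:
    """Mean squared SEM-normalized residual over the records."""
    if not records:
        raise ValueError("need at least one record")
    res = _residuals(records, model_kind, params)
    return float(np.mean(res ** 2))


def _residuals(records, model_kind, params) -> np.ndarray:
    return np.array([
        (r.delta_w_exp - predict_delta_w(model_kind, params, r.protocol)) / r.sem
        for r in records])


def q_min_rule(pair_changes_synapse: bool, tau_pre: float, tau_post: float) -> float:
    """Relaxed activation level fixed by the low-frequency pair experiment.

    If a pre-post pair leaves the synapse unchanged, the relaxed LTP scale
    must exactly cancel depression: ``q_min = 1/(1 + tau_post/tau_pre)``;
    otherwise ``q_min = 1`` (the balanced rule).
    """
    if tau_pre <= 0 or tau_post <= 0:
        raise ValueError("time constants must be > 0")
    if pair_changes_synapse:
        return 1.0
    return 1.0 / (1.0 + tau_post / tau_pre)


# --------------------------------------------------------------- grid search

def grid_search_fit(records: Sequence[ExperimentRecord],
                    bounds: ParameterBounds, model_kind: str = "cd",
                    n_refine: int = 2, refine_factor: int = 4) -> FitResult:
    """Brute-force grid scan with optional local refinement.

    Evaluates the SEM-normalized error at every point of the rectangular
    grid spanned by the free parameters, then (``n_refine`` times) re-grids
    the +-1-cell neighbourhood of the incumbent at ``refine_factor`` times
    the resolution. Deterministic for a fixed grid; ties break towards the
    first point in scan order.
    """
    if not records:
        raise ValueError("need at least one record")
    free = bounds.free_names
    if not free:
        raise ValueError("empty grid: no free parameters")

    # realize protocols once; simulation cost dominates
    prepared = [(realize(r.protocol), r) for r in records]

    def eval_point(values: dict) -> tuple[float, np.ndarray]:
        params = _make_params(model_kind, {**bounds.fixed, **values})
        res = np.empty(len(prepared))
        for k, ((pre, post), rec) in enumerate(prepared):
            if model_kind == "cd":
                dw = simulate_cd(pre, post, params).delta_w
            else:
                dw = simulate_triplet(pre, post, params).delta_w
            res[k] = (rec.delta_w_exp - dw) / rec.sem
        return float(np.mean(res ** 2)), res

    n_eval = 0

    def scan(axes: dict[str, np.ndarray], incumbent=None):
        nonlocal n_eval
        best = incumbent  # (error, values, residuals) or None
        for combo in itertools.product(*(axes[n] for n in free)):
            values = dict(zip(free, combo))
            if best is not None and values == best[1]:
                continue  # incumbent already evaluated
            err, res = eval_point(values)
            n_eval += 1
            if best is None or err < best[0]:
                best = (err, values, res)
        return best

    axes = {n: bounds.axis(n) for n in free}
    best = scan(axes)

    for _ in range(n_refine):
        new_axes = {}
        for n in free:
            ax = axes[n]
            i = int(np.argmin(np.abs(ax - best[1][n])))
            lo = ax[max(i - 1, 0)]
            hi = ax[min(i + 1, ax.size - 1)]
            n_pts = 2 * refine_factor + 1
            new_ax = bounds.axis(n, lo=lo, hi=hi, n=n_pts)
            # keep the incumbent coordinate exactly on the refined axis
            j = int(np.argmin(np.abs(new_ax - best[1][n])))
            new_ax[j] = best[1][n]
            new_axes[n] = new_ax
        best = scan(new_axes, incumbent=best)
        axes = new_axes

    return FitResult(best_params={**bounds.fixed, **best[1]}, error=best[0],
                     n_evaluations=n_eval, residuals=best[2])


def ablated_fit(records: Sequence[ExperimentRecord], bounds: ParameterBounds,
                disable: str, model_kind: str = "cd",
                **kwargs) -> FitResult:
    """Grid fit with adaptation components clamped off.

    ``disable`` is one of ``pre_adaptation``, ``post_adaptation`` or
    ``both``: the corresponding consumption fractions c_pre/c_post are fixed
    to zero and removed from the search.
    """
    clamp = {"pre_adaptation": ["c_pre"], "post_adaptation": ["c_post"],
             "both": ["c_pre", "c_post"]}
    if disable not in clamp:
        raise ValueError(f"unknown ablation {disable!r}")
    fixed = dict(bounds.fixed)
    for name in clamp[disable]:
        fixed[name] = 0.0
    new_bounds = ParameterBounds(bounds=bounds.bounds, fixed=fixed,
                                 n_points=bounds.n_points, spacing=bounds.spacing)
    return grid_search_fit(records, new_bounds, model_kind=model_kind, **kwargs)


# ------------------------------------------------------------------ I/O

def read_records(records_csv, protocols_json_path) -> List[ExperimentRecord]:
    """Load experiment records from CSV plus a protocol JSON file.

    The CSV needs columns ``protocol_id``, ``sem`` and one of ``delta_w_exp``
    or ``epsp_ratio`` (converted via ratio = 1 + dw). Malformed rows raise
    with their row number.
    """
    with open(protocols_json_path) as fh:
        protocols = protocols_from_json(fh.read())
    df = pd.read_csv(records_csv)
    if "protocol_id" not in df.columns or "sem" not in df.columns:
        raise ValueError("records CSV needs columns protocol_id, sem")
    has_dw = "delta_w_exp" in df.columns
    has_ratio = "epsp_ratio" in df.columns
    if not (has_dw or has_ratio):
        raise ValueError("records CSV needs delta_w_exp or epsp_ratio")
    records = []
    for idx, row in df.iterrows():
        rownum = idx + 2  # 1-based with header
        pid = str(row["protocol_id"])
        if pid not in protocols:
            raise ValueError(f"row {rownum}: unknown protocol_id {pid!r}")
        dw = float(row["delta_w_exp"]) if has_dw and pd.notna(row.get("delta_w_exp")) \
            else float(row["epsp_ratio"]) - 1.0
        sem = float(row["sem"])
        if not sem > 0:
            raise ValueError(f"row {rownum}: sem must be > 0")
        records.append(ExperimentRecord(protocols[pid], dw, sem))
    if not records:
        raise ValueError("no records in CSV")
    return records
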