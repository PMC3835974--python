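"""Packaged best-fit parameter sets and synthetic experiment generation.

The package ships the fitted parameter tables of the CD and triplet rules
for the four induction datasets (VC5, HC, SC23, VC23) as versioned JSON,
together with the brute-force search bounds. The measured weight changes of
those datasets are not redistributable, so fitting is exercised on
*synthetic* experiment records drawn from a known ground-truth model plus
Gaussian noise (:func:`generate_synthetic_records`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence, Union

import numpy as np

from .fitting import ExperimentRecord, ParameterBounds, predict_delta_w
from .params import CDParams, TripletParams, GATE_OPEN
from .protocols import InductionProtocol

__all__ = ["ParameterFixture", "load_params", "default_bounds",
           "generate_synthetic_records", "DATASETS", "MODELS"]

DATASETS = ("VC5", "HC", "SC23", "VC23")
MODELS = ("cd", "triplet")


@dataclass(frozen=True)
class ParameterFixture:
    dataset: str
    model: str
    params: Union[CDParams, TripletParams]
    published_error: float  # reference metadata only, not a test target
    provenance: dict
    notes: str = ""


def _raw() -> dict:
    with resources.files("synplast").joinpath("data/fitted_params.json").open() as fh:
        return json.load(fh)


def load_params(dataset: str, model: str) -> ParameterFixture:
    """Fitted parameters of one (dataset, model) combination.

    Absent printed entries follow the documented conventions: a null
    ``theta_q`` becomes the gate-open flag (-inf); absent recovery constants
    are stored inert alongside a zero consumption fraction; an absent
    triplet time constant stays ``None`` (its amplitude is zero).
    """
    if dataset not in DATASETS or model not in MODELS:
        raise KeyError(f"no fixture for dataset={dataset!r}, model={model!r}")
    entry = _raw()[model][dataset]
    pdict = dict(entry["params"])
    if model == "cd":
        if pdict.get("theta_q") is None:
            pdict["theta_q"] = GATE_OPEN
        params = CDParams(**pdict)
    else:
        params = TripletParams(**pdict)
    return ParameterFixture(dataset=dataset, model=model, params=params,
                            published_error=entry["published_error"],
                            provenance=entry["provenance"],
                            notes=entry.get("notes", ""))


def default_bounds(model: str, n_points: int = 8,
                   fixed: Optional[dict] = None) -> ParameterBounds:
    """The brute-force search bounds for one model kind."""
    raw = _raw()["bounds"]
    if model not in raw:
        raise KeyError(f"unknown model {model!r}")
    bounds = {k: tuple(v) for k, v in raw[model].items()}
    return ParameterBounds(bounds=bounds, fixed=dict(fixed or {}),
                           n_points=n_points)


def generate_synthetic_records(model_kind: str, params,
                               protocols: Sequence[InductionProtocol],
                               noise_sd: float, sem: float,
                               seed) -> list[ExperimentRecord]:
    """Synthetic experiment records from a known ground-truth model.

    Each record's measured weight change is the model prediction for its
    protocol plus Gaussian noise of standard deviation ``noise_sd``; all
    records carry the supplied ``sem``. Reproducible for a fixed seed.
    """
    if not protocols:
        raise ValueError("need at least one protocol")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not sem > 0:
        raise ValueError("sem must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    records = []
    for proto in protocols:
        dw = predict_delta_w(model_kind, params, proto)
        records.append(ExperimentRecord(proto, dw + rng.normal(0.0, noise_sd)
                                        if noise_sd else dw, sem))
    return records


def export_fixtures(path) -> None:
    """Dump the packaged fixture JSON verbatim to a user file."""
    with open(path, "w") as fh:
        json.dump(_raw(), fh, indent=2)
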