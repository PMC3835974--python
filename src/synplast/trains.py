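"""Spike trains: the elementary input of every plasticity simulation.

A :class:`SpikeTrain` is an ordered array of spike times (seconds) labelled
with the synaptic side it belongs to (``"pre"`` or ``"post"``). Times must be
finite, non-negative and non-decreasing; exactly coincident spikes on the
*same* side are rejected as degenerate input (a delta pulse cannot occur
twice at one instant), while pre/post coincidences are legal and resolved by
the integrators' documented tie-break.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

SIDES = ("pre", "post")


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times for one synaptic side.

    Parameters
    ----------
    times : array-like of float
        Spike times in seconds. Must be finite, >= 0 and non-decreasing;
        strictly increasing after validation (duplicates are rejected).
    side : {"pre", "post"}
    """

    times: np.ndarray
    side: str

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1:
            raise ValueError("spike times must be a 1-D sequence")
        if t.size and not np.all(np.isfinite(t)):
            raise ValueError("spike times must be finite")
        if t.size and t[0] < 0:
            raise ValueError("spike times must be >= 0")
        if np.any(np.diff(t) < 0):
            raise ValueError("spike times must be non-decreasing")
        if np.any(np.diff(t) == 0):
            raise ValueError(
                f"coincident {self.side!r} spikes are degenerate input"
            )
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def duration(self) -> float:
        """Time of the last spike (0.0 for an empty train)."""
        return float(self.times[-1]) if len(self) else 0.0

    def shifted(self, offset: float) -> "SpikeTrain":
        return SpikeTrain(self.times + offset, self.side)

    # ------------------------------------------------------------------ I/O
    def to_json(self) -> str:
        return json.dumps({"side": self.side, "times": self.times.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "SpikeTrain":
        obj = json.loads(text)
        return cls(np.asarray(obj["times"], dtype=float), obj["side"])


def trains_to_csv(path, *trains: SpikeTrain) -> None:
    """Write trains as a two-column CSV (time_s, side), full precision."""
    rows = [(t, tr.side) for tr in trains for t in tr.times]
    rows.sort()
    df = pd.DataFrame(rows, columns=["time_s", "side"])
    df.to_csv(path, index=False, float_format="%.17g")


def trains_from_csv(path) -> tuple[SpikeTrain, SpikeTrain]:
    """Read a (pre, post) pair of trains from a two-column CSV."""
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"time_s", "side"}.issubset(df.columns):
        raise ValueError("spike-train CSV needs columns time_s, side")
    out = []
    for side in SIDES:
        times = np.sort(df.loc[df["side"] == side, "time_s"].to_numpy(float))
        out.append(SpikeTrain(times, side))
    return tuple(out)
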