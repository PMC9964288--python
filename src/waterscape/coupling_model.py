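"""Coupling-coordination model over the spatial, psychological and
behavioral subsystem scores.

For subsystem levels u_1..u_k in (0, 1]:

* coupling index      C = [ prod(u) / mean(u)^k ]^(1/k), 1 iff all equal
* coordination index  T = sum(w_i u_i), default equal weights
* coordination degree D = sqrt(C * T), graded on a 10-level ladder with
  upper-inclusive bins (0.0, 0.1] -> 1 ... (0.9, 1.0] -> 10.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from waterscape.core_io import round_half_even

__all__ = [
    "SubsystemScores",
    "CouplingResult",
    "LEVEL_LABELS",
    "subsystem_scores",
    "coupling_degree",
    "coordination_index",
    "coupling_coordination",
    "couple_parks",
]

#: Floor for min-max scaled subsystem levels, to avoid zero products.
SCALE_FLOOR = 0.01

LEVEL_LABELS = {
    1: "Extreme maladjustment",
    2: "Severe maladjustment",
    3: "Moderate maladjustment",
    4: "Mild maladjustment",
    5: "Near maladjustment",
    6: "Poor coordination",
    7: "Mild coordination",
    8: "Moderate coordination",
    9: "Good coordination",
    10: "Excellent coordination",
}


@dataclass(frozen=True)
class SubsystemScores:
    park_id: str
    u: tuple[float, ...]  # ordered (spatial, psychological, behavioral)

    def __post_init__(self) -> None:
        if len(self.u) not in (2, 3):
            raise ValueError("expected 2 or 3 subsystem levels")
        if any(not 0.0 <= v <= 1.0 for v in self.u):
            raise ValueError(f"subsystem levels must lie in [0, 1], got {self.u}")


@dataclass(frozen=True)
class CouplingResult:
    park_id: str
    coupling_index: float
    coordination_index: float
    coupling_coordination_index: float
    level: int
    label: str


def subsystem_scores(
    table: pd.DataFrame, columns: Sequence[str], floor: float = SCALE_FLOOR
) -> list[SubsystemScores]:
    """Min-max scale each dimension column across parks to [floor, 1]."""
    if len(table) < 2:
        raise ValueError("need at least 2 parks for min-max scaling")
    scaled = {}
    for col in columns:
        vals = table[col].astype(float).to_numpy()
        lo, hi = vals.min(), vals.max()
        if hi == lo:
            raise ValueError(f"column {col!r} is constant; scaling undefined")
        scaled[col] = floor + (1.0 - floor) * (vals - lo) / (hi - lo)
    return [
        SubsystemScores(
            park_id=str(pid), u=tuple(float(scaled[col][i]) for col in columns)
        )
        for i, pid in enumerate(table["park_id"])
    ]


def coupling_degree(u: SubsystemScores | Sequence[float]) -> float:
    """C in [0, 1]; equals 1 iff all subsystem levels are equal."""
    vals = np.asarray(u.u if isinstance(u, SubsystemScores) else list(u), dtype=float)
    k = len(vals)
    if (vals == 0).any():
        warnings.warn("a subsystem level is 0; coupling degree collapses to 0", stacklevel=2)
        return 0.0
    if (vals < 0).any() or (vals > 1).any():
        raise ValueError("subsystem levels must lie in [0, 1]")
    return float((vals.prod() / vals.mean() ** k) ** (1.0 / k))


def coordination_index(
    u: SubsystemScores | Sequence[float], weights: Sequence[float] | None = None
) -> float:
    """T = weighted mean of subsystem levels."""
    vals = np.asarray(u.u if isinstance(u, SubsystemScores) else list(u), dtype=float)
    if weights is None:
        weights = np.full(len(vals), 1.0 / len(vals))
    else:
        weights = np.asarray(list(weights), dtype=float)
        if len(weights) != len(vals):
            raise ValueError(f"{len(weights)} weights for {len(vals)} subsystems")
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
    return float(np.dot(weights, vals))


def coupling_coordination(C: float, T: float) -> tuple[float, int, str]:
    """D = sqrt(C*T) rounded to 3 decimals, its ladder level, and the label."""
    if not (0.0 <= C <= 1.0 and 0.0 <= T <= 1.0):
        raise ValueError(f"C and T must lie in [0, 1], got C={C}, T={T}")
    d = round_half_even(math.sqrt(C * T), 3)
    level = min(10, max(1, math.ceil(d * 10 - 1e-9)))
    return d, level, LEVEL_LABELS[level]


def couple_parks(
    table: pd.DataFrame,
    columns: Sequence[str],
    weights: Sequence[float] | None = None,
    ndigits: int = 3,
) -> pd.DataFrame:
    """Full model for each park row; ``columns`` picks 2 or 3 dimensions."""
    results = []
    for scores in subsystem_scores(table, columns):
        c = coupling_degree(scores)
        t = coordination_index(scores, weights)
        d, level, label = coupling_coordination(c, t)
        results.append(
            CouplingResult(
                park_id=scores.park_id,
                coupling_index=round_half_even(c, ndigits),
                coordination_index=round_half_even(t, ndigits),
                coupling_coordination_index=d,
                level=level,
                label=label,
            )
        )
    return pd.DataFrame([r.__dict__ for r in results])
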