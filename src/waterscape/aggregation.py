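"""Indicator normalization, dimension composites, and natural-breaks grading.

Composites are arithmetic means of the indicator blocks (C1-C4 horizontal,
C5-C8 vertical, C9-C12 three-dimensional, C1-C12 overall); a geometric
aggregator is available but not the default — with a near-zero indicator the
product collapses, which the published scores contradict.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from waterscape.core_io import round_half_even

__all__ = [
    "IndicatorVector",
    "DimensionScores",
    "INDICATOR_NAMES",
    "normalize_indicators",
    "dimension_scores",
    "natural_breaks",
    "grade_by_value",
]

INDICATOR_NAMES = tuple(f"C{i}" for i in range(1, 13))

_BLOCKS = {
    "horizontal": INDICATOR_NAMES[0:4],
    "vertical": INDICATOR_NAMES[4:8],
    "three_dimensional": INDICATOR_NAMES[8:12],
}


@dataclass(frozen=True)
class IndicatorVector:
    park_id: str
    c: tuple[float, ...]
    raw: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.c) != 12:
            raise ValueError(f"expected 12 indicators, got {len(self.c)}")
        if not all(np.isfinite(self.c)):
            bad = [INDICATOR_NAMES[i] for i, v in enumerate(self.c) if not np.isfinite(v)]
            raise ValueError(f"non-finite normalized indicators: {bad}")


@dataclass(frozen=True)
class DimensionScores:
    park_id: str
    horizontal: float
    vertical: float
    three_dimensional: float
    overall: float
    grade: int | None = None


def normalize_indicators(
    raw: pd.DataFrame, bounds: dict[str, tuple[float, float]]
) -> list[IndicatorVector]:
    """Min-max normalize each indicator column with config-supplied bounds.

    ``bounds`` maps indicator name to (min, max); indicators absent from the
    mapping use identity bounds (0, 1), so a table that is already normalized
    passes through unchanged.
    """
    missing = [c for c in INDICATOR_NAMES if c not in raw.columns]
    if missing:
        raise ValueError(f"raw indicator table missing columns: {missing}")
    for name, (lo, hi) in bounds.items():
        if hi <= lo:
            raise ValueError(f"{name}: degenerate bounds ({lo}, {hi})")
    out = []
    for _, row in raw.iterrows():
        c = []
        for name in INDICATOR_NAMES:
            lo, hi = bounds.get(name, (0.0, 1.0))
            c.append((float(row[name]) - lo) / (hi - lo))
        out.append(
            IndicatorVector(
                park_id=str(row["park_id"]),
                c=tuple(c),
                raw=tuple(float(row[n]) for n in INDICATOR_NAMES),
            )
        )
    return out


def _aggregate(values: np.ndarray, method: str) -> float:
    if method == "arithmetic":
        return float(values.mean())
    if method == "geometric":
        if (values <= 0).any():
            raise ValueError("geometric mean undefined for nonpositive indicators")
        return float(np.exp(np.log(values).mean()))
    raise ValueError(f"unknown aggregation method {method!r}")


def dimension_scores(
    v: IndicatorVector, method: str = "arithmetic", ndigits: int = 4
) -> DimensionScores:
    """Block composites and the overall score, rounded for reporting."""
    c = np.asarray(v.c, dtype=float)
    parts = {
        name: _aggregate(c[i : i + 4], method)
        for name, i in (("horizontal", 0), ("vertical", 4), ("three_dimensional", 8))
    }
    overall = _aggregate(c, method)
    return DimensionScores(
        park_id=v.park_id,
        horizontal=round_half_even(parts["horizontal"], ndigits),
        vertical=round_half_even(parts["vertical"], ndigits),
        three_dimensional=round_half_even(parts["three_dimensional"], ndigits),
        overall=round_half_even(overall, ndigits),
    )


def scores_frame(vectors, method: str = "arithmetic") -> pd.DataFrame:
    rows = [dimension_scores(v, method=method) for v in vectors]
    df = pd.DataFrame(
        {
            "park_id": [r.park_id for r in rows],
            "horizontal": [r.horizontal for r in rows],
            "vertical": [r.vertical for r in rows],
            "three_dimensional": [r.three_dimensional for r in rows],
            "overall": [r.overall for r in rows],
        }
    )
    if len(df) >= 2 and df["overall"].nunique() >= 2:
        k = min(4, df["overall"].nunique())
        df["grade"] = natural_breaks(df["overall"].tolist(), k)
    return df


# ---------------------------------------------------------------------------
# Natural breaks (exact Fisher-Jenks by dynamic programming)
# ---------------------------------------------------------------------------


def _prefix_ssd(sorted_vals: np.ndarray):
    """O(1) within-class sum of squared deviations via prefix sums."""
    s1 = np.concatenate([[0.0], np.cumsum(sorted_vals)])
    s2 = np.concatenate([[0.0], np.cumsum(sorted_vals**2)])

    def ssd(i: int, j: int) -> float:  # half-open [i, j)
        n = j - i
        if n <= 1:
            return 0.0
        tot = s1[j] - s1[i]
        return float(s2[j] - s2[i] - tot * tot / n)

    return ssd


def natural_breaks(values, k: int) -> list[int]:
    """Exact minimal-SSD partition into k classes; class 1 = highest values.

    Dynamic programming over the sorted sequence guarantees the optimum (no
    heuristic reseeding), so results are deterministic.
    """
    vals = np.asarray(list(values), dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    n_distinct = len(np.unique(vals))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct values")
    n = len(vals)
    order = np.argsort(vals, kind="stable")
    sorted_vals = vals[order]
    ssd = _prefix_ssd(sorted_vals)

    # cost[c][j]: best SSD for the first j values in c classes
    cost = np.full((k + 1, n + 1), np.inf)
    split = np.zeros((k + 1, n + 1), dtype=int)
    cost[0][0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            for i in range(c - 1, j):
                cand = cost[c - 1][i] + ssd(i, j)
                if cand < cost[c][j] - 1e-12:
                    cost[c][j] = cand
                    split[c][j] = i
    # recover class of each sorted position; ascending blocks -> descending ids
    labels_sorted = np.empty(n, dtype=int)
    j = n
    for c in range(k, 0, -1):
        i = split[c][j]
        labels_sorted[i:j] = k - c + 1  # the last (highest) block gets class 1
        j = i
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels.tolist()


def grade_by_value(values, k: int) -> list[int]:
    """Alias of :func:`natural_breaks` named for the grading use case."""
    return natural_breaks(values, k)
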