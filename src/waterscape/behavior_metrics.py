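"""Behavioral metrics: heat-snapshot means and grades, visitor kernel
density, and behavior-observation summaries."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from waterscape.core_io import round_half_even

__all__ = [
    "HeatSnapshot",
    "VisitorPointSet",
    "BehaviorRecord",
    "DensitySurface",
    "thermal_mean",
    "thermal_grade",
    "kernel_density",
    "silverman_bandwidth",
    "behavior_summary",
    "density_grades",
    "DEFAULT_PURPOSE_MAP",
]

THERMAL_RANGE = (1.0, 8.0)

PURPOSE_CATEGORIES = ("sightseeing", "fitness", "social networking", "catering", "others")

#: Default mapping from observed activities to the five purpose categories.
DEFAULT_PURPOSE_MAP: dict[str, str] = {
    "sightseeing": "sightseeing",
    "viewing": "sightseeing",
    "photography": "sightseeing",
    "running": "fitness",
    "walking": "fitness",
    "cycling": "fitness",
    "basketball": "fitness",
    "badminton": "fitness",
    "tennis": "fitness",
    "playing table tennis": "fitness",
    "rope skipping": "fitness",
    "square dancing": "fitness",
    "square dance": "fitness",
    "taiji": "fitness",
    "mountaineering": "fitness",
    "chatting": "social networking",
    "playing cards": "social networking",
    "accompanying the family": "social networking",
    "accompanying family": "social networking",
    "spending time with family": "social networking",
    "fairs": "social networking",
    "eating": "catering",
    "picnicking": "catering",
    "passage": "others",
    "playing": "others",
    "walking the dog": "others",
    "dog walking": "others",
    "daze": "others",
}


@dataclass(frozen=True)
class HeatSnapshot:
    """One gridded heat-map interception; values on [1, 8] within the mask."""

    values: np.ndarray
    park_mask: np.ndarray
    timestamp: str = ""

    def __post_init__(self) -> None:
        if self.values.shape != self.park_mask.shape:
            raise ValueError("park_mask shape differs from values shape")
        masked = self.values[self.park_mask]
        if masked.size and (masked.min() < THERMAL_RANGE[0] or masked.max() > THERMAL_RANGE[1]):
            raise ValueError("heat values outside [1, 8] inside the park mask")


@dataclass(frozen=True)
class VisitorPointSet:
    points: np.ndarray  # (N, 2) planar coordinates in metres
    park_area_m2: float
    persons_per_point: float = 1.0

    def __post_init__(self) -> None:
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must have shape (N, 2)")
        if self.park_area_m2 <= 0:
            raise ValueError("park_area_m2 must be positive")
        if self.persons_per_point <= 0:
            raise ValueError("persons_per_point must be positive")

    @property
    def n_persons(self) -> float:
        return self.points.shape[0] * self.persons_per_point


@dataclass(frozen=True)
class BehaviorRecord:
    park_id: str
    recreation_time_h: float
    recreation_number: int
    recreation_frequency: float
    purposes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.recreation_time_h <= 0:
            raise ValueError("recreation_time_h must be positive")


@dataclass(frozen=True)
class DensitySurface:
    """Gridded density in persons/m^2 on cell centers."""

    values: np.ndarray
    cell_size_m: float

    def integral_persons(self) -> float:
        return float(self.values.sum() * self.cell_size_m**2)

    def mean_over(self, mask: np.ndarray | None = None) -> float:
        vals = self.values if mask is None else self.values[mask]
        return float(vals.mean())


def thermal_mean(snapshots: Sequence[HeatSnapshot]) -> float:
    """Mean of masked cell values pooled over all snapshots."""
    if not snapshots:
        raise ValueError("no heat snapshots")
    pooled = np.concatenate([s.values[s.park_mask].ravel() for s in snapshots])
    if pooled.size == 0:
        raise ValueError("all snapshots have empty masks")
    return float(pooled.mean())


def thermal_grade(mean: float, thresholds: tuple[float, float] = (2.0, 5.0)) -> str:
    """Grade a thermal mean: [1, lo] low, (lo, hi] sub, (hi, 8] high.

    Boundary semantics follow the published interval labels (2.0 is low,
    5.0 is sub).
    """
    lo, hi = thresholds
    if not THERMAL_RANGE[0] <= mean <= THERMAL_RANGE[1]:
        raise ValueError(f"thermal mean {mean} outside [1, 8]")
    if mean <= lo:
        return "low"
    if mean <= hi:
        return "sub"
    return "high"


def silverman_bandwidth(points: np.ndarray) -> float:
    """Silverman's rule on the pooled coordinate spread (isotropic kernel)."""
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if n < 2:
        return 1.0
    sigma = float(np.mean(pts.std(axis=0, ddof=1)))
    if sigma == 0:
        return 1.0
    return sigma * (4.0 / (3.0 * n)) ** 0.2


def kernel_density(
    points: VisitorPointSet,
    bandwidth_m: float | str = "auto",
    extent: tuple[float, float, float, float] | None = None,
    cell_size_m: float = 1.0,
) -> DensitySurface:
    """Gaussian KDE scaled so the surface integrates to the person count.

    ``extent`` is (xmin, xmax, ymin, ymax); when omitted it covers the points
    padded by 4 bandwidths so the kernels' mass is captured.
    """
    if points.points.shape[0] == 0:
        raise ValueError("no visitor points")
    if bandwidth_m == "auto":
        bw = silverman_bandwidth(points.points)
    else:
        bw = float(bandwidth_m)
    if bw <= 0:
        raise ValueError("bandwidth must be positive")
    pts = points.points.astype(float)
    if extent is None:
        pad = 4.0 * bw
        extent = (
            pts[:, 0].min() - pad,
            pts[:, 0].max() + pad,
            pts[:, 1].min() - pad,
            pts[:, 1].max() + pad,
        )
    xmin, xmax, ymin, ymax = extent
    xs = np.arange(xmin + cell_size_m / 2, xmax, cell_size_m)
    ys = np.arange(ymin + cell_size_m / 2, ymax, cell_size_m)
    gx, gy = np.meshgrid(xs, ys)
    norm = points.persons_per_point / (2.0 * np.pi * bw**2)
    dens = np.zeros_like(gx)
    for x0, y0 in pts:
        dens += np.exp(-((gx - x0) ** 2 + (gy - y0) ** 2) / (2.0 * bw**2))
    return DensitySurface(values=dens * norm, cell_size_m=cell_size_m)


def behavior_summary(
    records: Sequence[BehaviorRecord],
    purpose_map: Mapping[str, str] | None = None,
) -> dict:
    """Purpose-category ranking and mean recreation time.

    Activities are mapped to the five purpose categories via ``purpose_map``
    (default :data:`DEFAULT_PURPOSE_MAP`); unmapped activities are an error.
    Ranking breaks count ties lexicographically.
    """
    if not records:
        raise ValueError("no behavior records")
    purpose_map = purpose_map if purpose_map is not None else DEFAULT_PURPOSE_MAP
    counts = {cat: 0 for cat in PURPOSE_CATEGORIES}
    unmapped = []
    for rec in records:
        for activity in rec.purposes:
            key = activity.strip().lower()
            cat = purpose_map.get(key)
            if cat is None:
                unmapped.append(activity)
            else:
                counts[cat] += 1
    if unmapped:
        raise ValueError(f"activities with no purpose category: {sorted(set(unmapped))}")
    ranking = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    mean_time = round_half_even(float(np.mean([r.recreation_time_h for r in records])), 1)
    return {
        "mean_recreation_time_h": mean_time,
        "purpose_counts": dict(ranking),
        "purpose_ranking": [cat for cat, _ in ranking],
        "n_records": len(records),
    }


def density_grades(mean_densities: Sequence[float]) -> list[str]:
    """3-class natural-breaks density grades (high/medium/low)."""
    from waterscape.aggregation import natural_breaks

    labels = natural_breaks(list(mean_densities), k=3)
    names = {1: "high", 2: "medium", 3: "low"}
    return [names[v] for v in labels]
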