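"""Horizontal-space indicators from categorical cover rasters.

Covers species diversity (C1), evenness (C2), the hemeroby disturbance index
(C3), patch fragmentation (C4) and canopy density (C11).  Patch connectivity
is 8-neighborhood throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "LandCoverGrid",
    "HemerobyTable",
    "shannon_diversity",
    "pielou_evenness",
    "hemeroby_index",
    "fragmentation_index",
    "patch_counts",
    "canopy_density",
]

#: The nine vegetation-structure classes used as the "species" set for C1/C2.
VEGETATION_CLASSES = {
    1: "deciduous broadleaved forest (arbor)",
    2: "broad-leaved evergreen forest (arbor)",
    3: "deciduous needle-leaf forest (arbor)",
    4: "evergreen coniferous forest (arbor)",
    5: "deciduous broadleaved forest (shrub)",
    6: "broad-leaved evergreen forest (shrub)",
    7: "deciduous needle-leaf forest (shrub)",
    8: "evergreen coniferous forest (shrub)",
    9: "grass land",
}

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class LandCoverGrid:
    """Categorical cover raster with cell size and park mask."""

    codes: np.ndarray
    cell_size_m: float
    park_mask: np.ndarray
    class_labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")
        if self.codes.shape != self.park_mask.shape:
            raise ValueError("park_mask shape differs from codes shape")
        if not np.issubdtype(self.codes.dtype, np.integer):
            raise ValueError("cover codes must be integers")

    @property
    def cell_area_m2(self) -> float:
        return self.cell_size_m**2

    @property
    def park_area_ha(self) -> float:
        return int(self.park_mask.sum()) * self.cell_area_m2 / 1e4

    def class_areas_m2(self) -> dict[int, float]:
        """Area per class code inside the park mask, in square metres."""
        codes = self.codes[self.park_mask]
        values, counts = np.unique(codes, return_counts=True)
        return {int(v): float(c) * self.cell_area_m2 for v, c in zip(values, counts)}


@dataclass(frozen=True)
class HemerobyTable:
    """Map from cover class code to human-disturbance degree 1..h."""

    degree_of: dict[int, int]
    h: int

    def __post_init__(self) -> None:
        if self.h < 1:
            raise ValueError("h must be >= 1")
        for code, deg in self.degree_of.items():
            if not 1 <= deg <= self.h:
                raise ValueError(f"class {code}: degree {deg} outside [1, {self.h}]")


def _vegetation_proportions(grid: LandCoverGrid, vegetation_classes=None) -> np.ndarray:
    classes = set(vegetation_classes) if vegetation_classes is not None else set(VEGETATION_CLASSES)
    areas = grid.class_areas_m2()
    veg = np.array([areas[c] for c in sorted(classes) if c in areas and areas[c] > 0])
    if veg.size == 0:
        raise ValueError("no vegetation cells inside the park mask; diversity undefined")
    return veg / veg.sum()


def shannon_diversity(grid: LandCoverGrid, vegetation_classes=None) -> float:
    """Shannon diversity H = -sum(p_i ln p_i) over vegetation-class areas."""
    p = _vegetation_proportions(grid, vegetation_classes)
    return float(-np.sum(p * np.log(p)))


def shannon_from_proportions(proportions) -> float:
    """H for a known proportion vector (used as the analytic reference)."""
    p = np.asarray(proportions, dtype=float)
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def pielou_evenness(H: float, S: int) -> float:
    """Evenness J = H / ln S, defined only for S >= 2."""
    if S < 2:
        raise ValueError(f"evenness undefined for S={S} (< 2 classes)")
    if H < 0:
        raise ValueError("H must be nonnegative")
    return float(H / np.log(S))


def hemeroby_index(grid: LandCoverGrid, table: HemerobyTable) -> float:
    """Area-weighted disturbance HI = sum(i * S_i) / (h * S_A), in (0, 1]."""
    areas = grid.class_areas_m2()
    unmapped = sorted(set(areas) - set(table.degree_of))
    if unmapped:
        raise ValueError(f"cover classes without a hemeroby degree: {unmapped}")
    total = sum(areas.values())
    if total == 0:
        raise ValueError("empty park mask")
    weighted = sum(table.degree_of[c] * a for c, a in areas.items())
    return float(weighted / (table.h * total))


def patch_counts(grid: LandCoverGrid) -> dict[int, int]:
    """Connected-component (8-neighbor) patch count per class within the mask."""
    counts: dict[int, int] = {}
    for code in np.unique(grid.codes[grid.park_mask]):
        blob = (grid.codes == code) & grid.park_mask
        _, n = ndimage.label(blob, structure=_EIGHT_CONNECTED)
        counts[int(code)] = int(n)
    return counts


def fragmentation_index(grid: LandCoverGrid) -> float:
    """Total patches across all classes per hectare of park area."""
    if not grid.park_mask.any():
        raise ValueError("empty park mask")
    total_patches = sum(patch_counts(grid).values())
    return float(total_patches / grid.park_area_ha)


def canopy_density(canopy_mask: np.ndarray, plot_mask: np.ndarray) -> float:
    """Projected canopy area over plot area, in [0, 1]."""
    canopy_mask = np.asarray(canopy_mask, dtype=bool)
    plot_mask = np.asarray(plot_mask, dtype=bool)
    if canopy_mask.shape != plot_mask.shape:
        raise ValueError("canopy and plot masks differ in shape")
    if not plot_mask.any():
        raise ValueError("empty plot mask")
    if (canopy_mask & ~plot_mask).any():
        raise ValueError("canopy cells fall outside the plot mask")
    return float(canopy_mask.sum() / plot_mask.sum())
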