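"""Terrain-derived indicators from elevation and surface grids.

Implements the terrain-position "shape" metric (C7), profile curvature (C8),
tridimensional green volume (C10) and relief amplitude (C12).  Derivatives
use central finite differences on an odd-reflect-padded grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ElevationGrid",
    "SurfaceGrid",
    "terrain_position",
    "profile_curvature",
    "green_volume",
    "relief_amplitude",
]

#: Cells with squared gradient below this contribute zero curvature
#: (the denominator vanishes on flat ground).
GRADIENT_EPS = 1e-6

#: Default image resolution for green volume when none is carried by the grid.
DEFAULT_DELTA_D = 0.1


@dataclass(frozen=True)
class ElevationGrid:
    elevation_m: np.ndarray
    cell_size_m: float
    park_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")
        if self.elevation_m.shape != self.park_mask.shape:
            raise ValueError("park_mask shape differs from elevation shape")
        if not np.isfinite(self.elevation_m[self.park_mask]).all():
            raise ValueError("non-finite elevation inside the park mask")


@dataclass(frozen=True)
class SurfaceGrid:
    """Canopy-top / digital surface grid plus the vegetated-cell mask."""

    surface_m: np.ndarray
    delta_d_m: float
    vegetation_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.delta_d_m <= 0:
            raise ValueError("delta_d_m must be positive")
        if self.surface_m.shape != self.vegetation_mask.shape:
            raise ValueError("vegetation_mask shape differs from surface shape")


def terrain_position(dem: ElevationGrid) -> tuple[np.ndarray, float]:
    """Per-cell difference between a cell and the mean of its 8 neighbors.

    Border cells use the neighbors that exist.  Returns the per-cell grid and
    the plain mean over the park mask (which may be negative).
    """
    z = np.asarray(dem.elevation_m, dtype=float)
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("grid must be at least 3x3")
    if not dem.park_mask.any():
        raise ValueError("empty park mask")
    total = np.zeros_like(z)
    count = np.zeros_like(z)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            src = z[
                max(di, 0) : z.shape[0] + min(di, 0),
                max(dj, 0) : z.shape[1] + min(dj, 0),
            ]
            dst_total = total[
                max(-di, 0) : z.shape[0] + min(-di, 0),
                max(-dj, 0) : z.shape[1] + min(-dj, 0),
            ]
            dst_count = count[
                max(-di, 0) : z.shape[0] + min(-di, 0),
                max(-dj, 0) : z.shape[1] + min(-dj, 0),
            ]
            dst_total += src
            dst_count += 1
    position = z - total / count
    return position, float(position[dem.park_mask].mean())


def _derivatives(z: np.ndarray, h: float):
    """Central-difference p, q, r, s, t with odd-reflect (linear
    extrapolation) padding, so planes stay curvature-free at the boundary.

    x runs along columns, y along rows.
    """
    zp = np.pad(z, 1, mode="reflect", reflect_type="odd")
    c = zp[1:-1, 1:-1]
    east, west = zp[1:-1, 2:], zp[1:-1, :-2]
    south, north = zp[2:, 1:-1], zp[:-2, 1:-1]
    se, nw = zp[2:, 2:], zp[:-2, :-2]
    sw, ne = zp[2:, :-2], zp[:-2, 2:]
    p = (east - west) / (2 * h)
    q = (south - north) / (2 * h)
    r = (east - 2 * c + west) / h**2
    t = (south - 2 * c + north) / h**2
    s = (se - sw - ne + nw) / (4 * h**2)
    return p, q, r, s, t


def profile_curvature(dem: ElevationGrid) -> tuple[np.ndarray, float]:
    """Profile curvature Kp per cell and its mean over the park mask.

    Kp = -(r p^2 + 2 s p q + t q^2) / [(p^2+q^2)(p^2+q^2+1)^{3/2}]; cells with
    vanishing gradient are set to 0.
    """
    z = np.asarray(dem.elevation_m, dtype=float)
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("grid must be at least 3x3")
    p, q, r, s, t = _derivatives(z, dem.cell_size_m)
    g2 = p**2 + q**2
    flat = g2 < GRADIENT_EPS
    g2_safe = np.where(flat, 1.0, g2)
    kp = -(r * p**2 + 2 * s * p * q + t * q**2) / (g2_safe * (g2_safe + 1.0) ** 1.5)
    kp[flat] = 0.0
    return kp, float(kp[dem.park_mask].mean())


def green_volume(dsm: SurfaceGrid, dem: ElevationGrid) -> float:
    """Volume between canopy surface and ground over vegetated cells (m^3)."""
    if dsm.surface_m.shape != dem.elevation_m.shape:
        raise ValueError(
            f"surface shape {dsm.surface_m.shape} != elevation shape {dem.elevation_m.shape}"
        )
    diff = np.abs(dsm.surface_m - dem.elevation_m)[dsm.vegetation_mask]
    return float(dsm.delta_d_m**2 * diff.sum())


def relief_amplitude(dem: ElevationGrid) -> float:
    """Max minus min elevation within the park mask (m)."""
    if not dem.park_mask.any():
        raise ValueError("empty park mask")
    vals = dem.elevation_m[dem.park_mask]
    return float(vals.max() - vals.min())
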