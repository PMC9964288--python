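"""Panorama-based indicators: layer superposition (C5), colorfulness (C6),
and sky fraction (C9).

Layer superposition has no published construction; this module realizes it as
a vertical-transition tally over a fixed 6-band partition of the image —
outputs carry a ``construction`` note flagging this.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PanoramaImage",
    "LayerMatrix",
    "LAYER_CLASSES",
    "build_layer_matrix",
    "layer_superposition",
    "colorfulness",
    "sky_fraction",
    "park_mean",
]

LAYER_CLASSES = ("sky", "canopy", "understory", "ground", "water", "hardscape")
N_BANDS = 6

#: HSV rule for sky pixels when no ground-truth mask is available:
#: hue within blue range, at least moderately bright, or nearly white (haze).
DEFAULT_SKY_HSV = {"hue_min": 0.5, "hue_max": 0.72, "value_min": 0.55, "sat_max_white": 0.12}


@dataclass(frozen=True)
class PanoramaImage:
    rgb: np.ndarray
    sky_mask: np.ndarray | None = None
    layer_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError(f"rgb must have shape (H, W, 3), got {self.rgb.shape}")
        for name in ("sky_mask", "layer_labels"):
            arr = getattr(self, name)
            if arr is not None and arr.shape != self.rgb.shape[:2]:
                raise ValueError(f"{name} shape {arr.shape} != image shape {self.rgb.shape[:2]}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.rgb.shape[:2]


@dataclass(frozen=True)
class LayerMatrix:
    """Square tally of vertical band-to-band layer transitions."""

    tally: np.ndarray

    def __post_init__(self) -> None:
        if self.tally.ndim != 2 or self.tally.shape[0] != self.tally.shape[1]:
            raise ValueError("tally must be square")
        if (self.tally < 0).any():
            raise ValueError("tally counts must be nonnegative")

    @property
    def total(self) -> float:
        return float(self.tally.sum())


def _band_slices(height: int, n_bands: int = N_BANDS) -> list[slice]:
    edges = np.linspace(0, height, n_bands + 1).astype(int)
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:]) if b > a]


def build_layer_matrix(image: PanoramaImage, n_classes: int | None = None) -> LayerMatrix:
    """Tally ordered (band k, band k+1) label pairs per image column.

    Each of the 6 vertical bands contributes its modal label per column (ties
    break to the smallest class code).  Diagonal entries are same-class
    persistences.
    """
    if image.layer_labels is None:
        raise ValueError(
            "layer_labels missing; supply a segmentation or configure one "
            "(synthetic scenes carry ground-truth labels)"
        )
    labels = np.asarray(image.layer_labels, dtype=int)
    k = n_classes if n_classes is not None else max(len(LAYER_CLASSES), int(labels.max()) + 1)
    height, width = labels.shape
    slices = _band_slices(height)
    band_labels = np.empty((len(slices), width), dtype=int)
    for b, sl in enumerate(slices):
        block = labels[sl, :]
        counts = np.stack([(block == c).sum(axis=0) for c in range(k)])
        band_labels[b] = counts.argmax(axis=0)  # argmax takes the smallest code on ties
    tally = np.zeros((k, k), dtype=float)
    for b in range(len(slices) - 1):
        np.add.at(tally, (band_labels[b], band_labels[b + 1]), 1.0)
    return LayerMatrix(tally=tally)


def layer_superposition(matrix: LayerMatrix) -> float:
    """Trace over total of the transition tally, in [0, 1]."""
    if matrix.total <= 0:
        raise ValueError("layer matrix has zero total count")
    return float(np.trace(matrix.tally) / matrix.total)


def colorfulness(image: PanoramaImage) -> float:
    """Opponent-channel colorfulness: sigma_rgyb + 0.3 * mu_rgyb.

    rg = R - G, yb = (R + G)/2 - B; statistics over the full pixel population
    in double precision.  Zero iff the image is achromatic.
    """
    rgb = image.rgb.astype(np.float64)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    rg = r - g
    yb = 0.5 * (r + g) - b
    sigma = np.hypot(rg.std(), yb.std())
    mu = np.hypot(rg.mean(), yb.mean())
    return float(sigma + 0.3 * mu)


def _hsv_sky_mask(rgb: np.ndarray, rule: dict) -> np.ndarray:
    from skimage.color import rgb2hsv

    hsv = rgb2hsv(rgb.astype(np.float64) / 255.0)
    hue, sat, val = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    blue = (hue >= rule["hue_min"]) & (hue <= rule["hue_max"]) & (val >= rule["value_min"])
    white = (sat <= rule["sat_max_white"]) & (val >= rule["value_min"])
    return blue | white


def sky_fraction(image: PanoramaImage, hsv_rule: dict | None = None) -> float:
    """Fraction of pixels that are sky, from the ground-truth mask if present,
    otherwise from an HSV threshold rule."""
    if image.sky_mask is not None:
        mask = np.asarray(image.sky_mask, dtype=bool)
    elif hsv_rule is not None:
        mask = _hsv_sky_mask(image.rgb, hsv_rule)
    else:
        raise ValueError("no sky_mask and no HSV threshold rule configured")
    return float(mask.mean())


def park_mean(values: Iterable[float]) -> float:
    """Per-park indicator = arithmetic mean over the park's panoramas."""
    vals = list(values)
    if not vals:
        raise ValueError("no panoramas for this park")
    return float(np.mean(vals))
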