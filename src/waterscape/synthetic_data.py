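"""Synthetic scene generation with known ground truth.

Every generator is a pure function of (spec, seed): land-cover grids with
exact class proportions, terrain with exact relief, banded panoramas with
exact sky fraction, review corpora whose lexicon-scored emotional values hit
their targets exactly, and heat/visitor fields built from the same Gaussian
bump mixture.  ``write_scene`` lays a multi-park scene out on disk in the
format :func:`waterscape.core_io.run_pipeline` consumes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from waterscape.core_io import ReviewRecord, Raster, write_raster
from waterscape.landcover_metrics import LandCoverGrid, VEGETATION_CLASSES
from waterscape.terrain_metrics import ElevationGrid, SurfaceGrid
from waterscape.image_metrics import PanoramaImage
from waterscape.behavior_metrics import HeatSnapshot, VisitorPointSet
from waterscape.fixtures import load_terms

__all__ = [
    "SceneSpec",
    "gen_landcover",
    "gen_terrain",
    "gen_panorama",
    "gen_reviews",
    "gen_heat_and_visitors",
    "write_scene",
]

#: Default per-class display colors (RGB 0-255).
DEFAULT_PALETTE = {
    0: (135, 206, 235),  # sky
    1: (34, 139, 34),  # arbor canopy
    2: (85, 107, 47),  # shrub
    9: (124, 180, 80),  # grass
    20: (70, 130, 180),  # water
    21: (128, 128, 128),  # hardscape
}

_NEUTRAL_FILLERS = ("the", "park", "by", "river", "path", "walk", "today")


@dataclass(frozen=True)
class SceneSpec:
    """Ground-truth parameters for one synthetic park."""

    park_id: str = "PARK"
    seed: int = 0
    shape: tuple[int, int] = (60, 60)
    cell_size_m: float = 15.0
    class_proportions: dict[int, float] = field(
        default_factory=lambda: {1: 0.5, 9: 0.3, 21: 0.2}
    )
    patchiness: float = 3.0
    relief_m: float = 5.0
    canopy_height_m: tuple[float, float] = (5.0, 0.0)  # (mean, spread)
    sky_fraction: float = 0.3
    pano_shape: tuple[int, int] = (120, 240)
    n_panoramas: int = 3
    palette: dict[int, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_PALETTE)
    )
    n_landscape_reviews: int = 20
    n_park_reviews: int = 60
    landscape_value: float = 7.0
    park_value: float = 5.0
    heat_spec: tuple[dict, ...] = (
        {"cx": 0.5, "cy": 0.5, "intensity": 6.0, "width_frac": 0.2},
    )
    n_snapshots: int = 3
    n_visitors: int = 100
    recreation_time_h: float = 1.5
    recreation_number: int = 500
    recreation_frequency: float = 2.0
    purposes: tuple[str, ...] = ("sightseeing", "walking", "chatting")

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, expected 1")
        if any(p < 0 for p in self.class_proportions.values()):
            raise ValueError("class proportions must be nonnegative")
        if not 0.0 <= self.sky_fraction <= 1.0:
            raise ValueError("sky_fraction must lie in [0, 1]")
        if self.n_landscape_reviews > self.n_park_reviews:
            raise ValueError("landscape reviews cannot exceed total park reviews")


def _rng(spec: SceneSpec, salt: int) -> np.random.Generator:
    return np.random.default_rng((spec.seed, salt))


def _smooth_field(rng: np.random.Generator, shape, scale: float) -> np.ndarray:
    return gaussian_filter(rng.standard_normal(shape), sigma=max(scale, 1e-9))


def gen_landcover(spec: SceneSpec) -> LandCoverGrid:
    """Threshold a smoothed noise field at class-proportion quantiles.

    Empirical proportions match the spec up to quantile discreteness (well
    within 0.02 at 200x200).
    """
    codes_sorted = sorted(spec.class_proportions)
    props = np.array([spec.class_proportions[c] for c in codes_sorted])
    field_ = _smooth_field(_rng(spec, 1), spec.shape, spec.patchiness)
    cum = np.cumsum(props)[:-1]
    thresholds = np.quantile(field_, cum) if cum.size else np.array([])
    idx = np.searchsorted(thresholds, field_, side="right")
    codes = np.asarray(codes_sorted, dtype=np.int64)[idx]
    labels = {c: VEGETATION_CLASSES.get(c, f"class {c}") for c in codes_sorted}
    return LandCoverGrid(
        codes=codes,
        cell_size_m=spec.cell_size_m,
        park_mask=np.ones(spec.shape, dtype=bool),
        class_labels=labels,
    )


def vegetation_mask_of(grid: LandCoverGrid) -> np.ndarray:
    veg = np.isin(grid.codes, list(VEGETATION_CLASSES))
    return veg & grid.park_mask


def gen_terrain(
    spec: SceneSpec, vegetation_mask: np.ndarray | None = None
) -> tuple[ElevationGrid, SurfaceGrid]:
    """Smooth random DEM rescaled to the target relief exactly; DSM adds
    canopy heights on vegetated cells."""
    if spec.relief_m < 0:
        raise ValueError("relief_m must be nonnegative")
    rng = _rng(spec, 2)
    base = _smooth_field(rng, spec.shape, spec.patchiness * 2)
    if spec.relief_m == 0 or base.max() == base.min():
        dem_values = np.zeros(spec.shape)
    else:
        dem_values = (base - base.min()) / (base.max() - base.min()) * spec.relief_m
    if vegetation_mask is None:
        vegetation_mask = vegetation_mask_of(gen_landcover(spec))
    mean_h, spread_h = spec.canopy_height_m
    heights = np.zeros(spec.shape)
    if vegetation_mask.any():
        if spread_h > 0:
            sampled = rng.normal(mean_h, spread_h, size=int(vegetation_mask.sum()))
            heights[vegetation_mask] = np.clip(sampled, 0.1, None)
        else:
            heights[vegetation_mask] = mean_h
    mask = np.ones(spec.shape, dtype=bool)
    dem = ElevationGrid(elevation_m=dem_values, cell_size_m=spec.cell_size_m, park_mask=mask)
    dsm = SurfaceGrid(
        surface_m=dem_values + heights,
        delta_d_m=spec.cell_size_m,
        vegetation_mask=vegetation_mask,
    )
    return dem, dsm


def gen_panorama(spec: SceneSpec, index: int = 0) -> PanoramaImage:
    """Banded panorama: sky rows on top (fraction exact to one row), then
    canopy / understory / ground bands from the palette."""
    height, width = spec.pano_shape
    sky_rows = int(round(spec.sky_fraction * height))
    labels = np.empty((height, width), dtype=int)
    labels[:sky_rows, :] = 0  # sky
    rest = height - sky_rows
    # split the non-sky part into canopy/understory/ground (40/30/30)
    canopy_rows = int(round(0.4 * rest))
    under_rows = int(round(0.3 * rest))
    labels[sky_rows : sky_rows + canopy_rows, :] = 1
    labels[sky_rows + canopy_rows : sky_rows + canopy_rows + under_rows, :] = 2
    labels[sky_rows + canopy_rows + under_rows :, :] = 3
    layer_palette = {
        0: spec.palette.get(0, DEFAULT_PALETTE[0]),
        1: spec.palette.get(1, DEFAULT_PALETTE[1]),
        2: spec.palette.get(2, DEFAULT_PALETTE[2]),
        3: spec.palette.get(9, DEFAULT_PALETTE[9]),
    }
    rgb = np.zeros((height, width, 3), dtype=np.uint8)
    for code, color in layer_palette.items():
        rgb[labels == code] = color
    return PanoramaImage(rgb=rgb, sky_mask=labels == 0, layer_labels=labels)


def _hit_counts(value: float) -> tuple[int, int]:
    """Positive/negative token counts whose lexicon score equals ``value``.

    Exact whenever (value - 5)/5 has a denominator <= 100 (every 1- or
    2-decimal target does); otherwise the closest such rational.
    """
    if not 0.0 <= value <= 10.0:
        raise ValueError(f"emotional value {value} outside [0, 10]")
    frac = Fraction(value - 5.0).limit_denominator(100) / 5
    a, b = frac.numerator, frac.denominator
    return b + a, b - a  # (pos - neg)/(pos + neg) == a/b


def _make_text(rng: np.random.Generator, value: float, positive, negative) -> str:
    pos, neg = _hit_counts(value)
    tokens = list(rng.choice(positive, size=pos))
    tokens += list(rng.choice(negative, size=neg))
    tokens += list(rng.choice(_NEUTRAL_FILLERS, size=2))
    rng.shuffle(tokens)
    return " ".join(tokens)


def gen_reviews(spec: SceneSpec) -> list[ReviewRecord]:
    """Review corpus whose default-scorer emotional values hit the spec
    targets exactly.

    Landscape reviews each score ``landscape_value``; the remaining
    park-targeted reviews score the level that brings the all-review mean to
    ``park_value``.
    """
    rng = _rng(spec, 3)
    positive = load_terms("lexicon_positive.txt")
    negative = load_terms("lexicon_negative.txt")
    n_l, n_p = spec.n_landscape_reviews, spec.n_park_reviews
    records = [
        ReviewRecord(spec.park_id, "landscape", _make_text(rng, spec.landscape_value, positive, negative))
        for _ in range(n_l)
    ]
    n_rest = n_p - n_l
    if n_rest > 0:
        rest_value = (n_p * spec.park_value - n_l * spec.landscape_value) / n_rest
        if not 0.0 <= rest_value <= 10.0:
            raise ValueError(
                f"park/landscape value targets need non-landscape score {rest_value:.2f}, "
                "outside [0, 10]"
            )
        records += [
            ReviewRecord(spec.park_id, "park", _make_text(rng, rest_value, positive, negative))
            for _ in range(n_rest)
        ]
    return records


def _bump_field(spec: SceneSpec, jitter: float = 1.0) -> np.ndarray:
    nrows, ncols = spec.shape
    ys, xs = np.mgrid[0:nrows, 0:ncols]
    xs = (xs + 0.5) * spec.cell_size_m
    ys = (ys + 0.5) * spec.cell_size_m
    width_x = ncols * spec.cell_size_m
    width_y = nrows * spec.cell_size_m
    out = np.full(spec.shape, 1.0)
    for bump in spec.heat_spec:
        cx, cy = bump["cx"] * width_x, bump["cy"] * width_y
        w = bump["width_frac"] * min(width_x, width_y)
        amp = (bump["intensity"] - 1.0) * jitter
        out += amp * np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * w**2))
    return np.clip(out, 1.0, 8.0)


def gen_heat_and_visitors(spec: SceneSpec) -> tuple[list[HeatSnapshot], VisitorPointSet]:
    """Clipped Gaussian-bump heat snapshots plus visitor points drawn from the
    same bump mixture."""
    for bump in spec.heat_spec:
        if not 1.0 <= bump["intensity"] <= 8.0:
            raise ValueError(f"bump intensity {bump['intensity']} outside [1, 8]")
    rng = _rng(spec, 4)
    mask = np.ones(spec.shape, dtype=bool)
    snapshots = []
    for i in range(spec.n_snapshots):
        jitter = 1.0 if spec.n_snapshots == 1 else 0.9 + 0.2 * i / (spec.n_snapshots - 1)
        snapshots.append(
            HeatSnapshot(values=_bump_field(spec, jitter), park_mask=mask, timestamp=f"t{i}")
        )
    nrows, ncols = spec.shape
    width_x, width_y = ncols * spec.cell_size_m, nrows * spec.cell_size_m
    if spec.heat_spec:
        weights = np.array([b["intensity"] - 1.0 for b in spec.heat_spec], dtype=float)
        weights = weights / weights.sum() if weights.sum() > 0 else None
    else:
        weights = None
    points = np.empty((spec.n_visitors, 2))
    for i in range(spec.n_visitors):
        if weights is None:
            points[i] = rng.uniform([0, 0], [width_x, width_y])
        else:
            bump = spec.heat_spec[rng.choice(len(spec.heat_spec), p=weights)]
            w = bump["width_frac"] * min(width_x, width_y)
            pt = rng.normal([bump["cx"] * width_x, bump["cy"] * width_y], w)
            points[i] = np.clip(pt, [0, 0], [width_x, width_y])
    visitors = VisitorPointSet(points=points, park_area_m2=width_x * width_y)
    return snapshots, visitors


# ---------------------------------------------------------------------------
# Scene directory writer
# ---------------------------------------------------------------------------


def write_scene(specs: list[SceneSpec], outdir: str | Path) -> Path:
    """Write a complete multi-park scene directory.

    Layout::

        scene.json                 manifest + ground truth
        reviews.csv                all parks' reviews
        behavior.csv               one observation row per park
        <park_id>/landcover.asc    categorical cover grid
        <park_id>/dem.asc          ground elevation
        <park_id>/dsm.asc          canopy-top surface
        <park_id>/vegmask.asc      vegetated-cell mask (0/1)
        <park_id>/heat_<i>.asc     heat snapshots
        <park_id>/visitors.csv     visitor coordinates (m)
        <park_id>/pano_<i>.png     panoramas (+ _sky.png, _labels.asc)
    """
    import pandas as pd
    from PIL import Image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ids = [s.park_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate park_id in scene specs")

    manifest: dict = {"parks": [], "version": 1}
    review_rows = []
    behavior_rows = []
    for spec in specs:
        pdir = outdir / spec.park_id
        pdir.mkdir(exist_ok=True)
        grid = gen_landcover(spec)
        vegmask = vegetation_mask_of(grid)
        dem, dsm = gen_terrain(spec, vegetation_mask=vegmask)
        snapshots, visitors = gen_heat_and_visitors(spec)

        write_raster(
            pdir / "landcover.asc",
            Raster(grid.codes.astype(float), spec.cell_size_m, grid.park_mask, "categorical"),
        )
        write_raster(
            pdir / "dem.asc", Raster(dem.elevation_m, spec.cell_size_m, dem.park_mask)
        )
        write_raster(
            pdir / "dsm.asc", Raster(dsm.surface_m, spec.cell_size_m, dem.park_mask)
        )
        write_raster(
            pdir / "vegmask.asc",
            Raster(vegmask.astype(float), spec.cell_size_m, dem.park_mask, "categorical"),
        )
        for i, snap in enumerate(snapshots):
            write_raster(
                pdir / f"heat_{i}.asc",
                Raster(snap.values, spec.cell_size_m, snap.park_mask),
            )
        pd.DataFrame(visitors.points, columns=["x_m", "y_m"]).to_csv(
            pdir / "visitors.csv", index=False, lineterminator="\n"
        )
        for i in range(spec.n_panoramas):
            pano = gen_panorama(spec, i)
            Image.fromarray(pano.rgb).save(pdir / f"pano_{i}.png")
            Image.fromarray((pano.sky_mask * 255).astype(np.uint8)).save(
                pdir / f"pano_{i}_sky.png"
            )
            write_raster(
                pdir / f"pano_{i}_labels.asc",
                Raster(
                    pano.layer_labels.astype(float),
                    1.0,
                    np.ones(pano.shape, dtype=bool),
                    "categorical",
                ),
            )
        for rec in gen_reviews(spec):
            review_rows.append({"park_id": rec.park_id, "target": rec.target, "text": rec.text})
        behavior_rows.append(
            {
                "park_id": spec.park_id,
                "recreation_time_h": spec.recreation_time_h,
                "recreation_number": spec.recreation_number,
                "recreation_frequency": spec.recreation_frequency,
                "purposes": ";".join(spec.purposes),
            }
        )

        from waterscape.terrain_metrics import green_volume

        manifest["parks"].append(
            {
                "park_id": spec.park_id,
                "cell_size_m": spec.cell_size_m,
                "n_panoramas": spec.n_panoramas,
                "n_snapshots": spec.n_snapshots,
                "spec": _spec_dict(spec),
                "truth": {
                    "class_proportions": {
                        str(k): v for k, v in spec.class_proportions.items()
                    },
                    "relief_m": spec.relief_m,
                    "sky_fraction": round(spec.sky_fraction * spec.pano_shape[0])
                    / spec.pano_shape[0],
                    "green_volume_m3": green_volume(dsm, dem),
                    "n_visitors": spec.n_visitors,
                    "landscape_value": spec.landscape_value,
                    "park_value": spec.park_value,
                },
            }
        )

    pd.DataFrame(
        review_rows, columns=["park_id", "target", "text"]
    ).to_csv(outdir / "reviews.csv", index=False, lineterminator="\n")
    pd.DataFrame(
        behavior_rows,
        columns=[
            "park_id",
            "recreation_time_h",
            "recreation_number",
            "recreation_frequency",
            "purposes",
        ],
    ).to_csv(outdir / "behavior.csv", index=False, lineterminator="\n")
    (outdir / "scene.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return outdir


def _spec_dict(spec: SceneSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["class_proportions"] = {str(k): v for k, v in d["class_proportions"].items()}
    d["palette"] = {str(k): list(v) for k, v in d["palette"].items()}
    d["heat_spec"] = list(d["heat_spec"])
    return d
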