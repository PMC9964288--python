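"""Stage implementations behind :func:`waterscape.core_io.run_pipeline`.

Each stage consumes a scene directory (see
:func:`waterscape.synthetic_data.write_scene` for the layout) and returns
plain DataFrames; `run_pipeline` owns writing and stage-failure reporting.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from waterscape import (
    aggregation,
    behavior_metrics,
    coupling_model,
    image_metrics,
    landcover_metrics,
    sentiment_analysis,
    terrain_metrics,
)
from waterscape.core_io import RunConfig, read_raster, read_reviews, round_half_even
from waterscape.landcover_metrics import HemerobyTable, LandCoverGrid, VEGETATION_CLASSES

DEFAULT_HEMEROBY_H = 7


def load_manifest(scene_dir: Path) -> dict:
    path = Path(scene_dir) / "scene.json"
    if not path.exists():
        raise FileNotFoundError(f"no scene.json in {scene_dir}")
    return json.loads(path.read_text(encoding="utf-8"))


def _park_ids(manifest: dict) -> list[str]:
    return [p["park_id"] for p in manifest.get("parks", [])]


def _default_hemeroby(codes: set[int]) -> HemerobyTable:
    # Natural vegetation is low-disturbance; anything unclassified counts as
    # artificial surface at the top of a 7-degree ladder.
    degree_of = {c: (2 if c in VEGETATION_CLASSES else DEFAULT_HEMEROBY_H) for c in codes}
    return HemerobyTable(degree_of=degree_of, h=DEFAULT_HEMEROBY_H)


def _raw_indicators(config: RunConfig, park_dir: Path, park: dict) -> dict[str, float]:
    cell = park.get("cell_size_m", config.cell_size_m)
    lc_raster = read_raster(park_dir / "landcover.asc", kind="categorical")
    grid = LandCoverGrid(
        codes=lc_raster.values,
        cell_size_m=cell,
        park_mask=lc_raster.mask,
        class_labels={c: VEGETATION_CLASSES.get(c, f"class {c}") for c in np.unique(lc_raster.values)},
    )
    veg_present = sorted(
        set(np.unique(grid.codes[grid.park_mask]).tolist()) & set(VEGETATION_CLASSES)
    )
    h_val = landcover_metrics.shannon_diversity(grid)
    c2 = landcover_metrics.pielou_evenness(h_val, len(veg_present)) if len(veg_present) >= 2 else 0.0
    hem = (
        HemerobyTable(config.hemeroby_degrees, max(config.hemeroby_degrees.values()))
        if config.hemeroby_degrees
        else _default_hemeroby(set(np.unique(grid.codes[grid.park_mask]).tolist()))
    )
    c3 = landcover_metrics.hemeroby_index(grid, hem)
    c4 = landcover_metrics.fragmentation_index(grid)

    dem_raster = read_raster(park_dir / "dem.asc")
    dsm_raster = read_raster(park_dir / "dsm.asc")
    veg_raster = read_raster(park_dir / "vegmask.asc", kind="categorical")
    vegmask = veg_raster.values.astype(bool) & veg_raster.mask
    dem = terrain_metrics.ElevationGrid(
        elevation_m=dem_raster.values, cell_size_m=cell, park_mask=dem_raster.mask
    )
    dsm = terrain_metrics.SurfaceGrid(
        surface_m=dsm_raster.values, delta_d_m=cell, vegetation_mask=vegmask
    )
    _, c7 = terrain_metrics.terrain_position(dem)
    _, c8 = terrain_metrics.profile_curvature(dem)
    c10 = terrain_metrics.green_volume(dsm, dem)
    c12 = terrain_metrics.relief_amplitude(dem)
    c11 = landcover_metrics.canopy_density(vegmask, dem_raster.mask)

    c5s, c6s, c9s = [], [], []
    for i in range(park.get("n_panoramas", 0)):
        from PIL import Image

        rgb = np.asarray(Image.open(park_dir / f"pano_{i}.png").convert("RGB"))
        sky = np.asarray(Image.open(park_dir / f"pano_{i}_sky.png")) > 127
        labels = read_raster(park_dir / f"pano_{i}_labels.asc", kind="categorical").values
        pano = image_metrics.PanoramaImage(rgb=rgb, sky_mask=sky, layer_labels=labels)
        c5s.append(image_metrics.layer_superposition(image_metrics.build_layer_matrix(pano)))
        c6s.append(image_metrics.colorfulness(pano))
        c9s.append(image_metrics.sky_fraction(pano))
    c5 = image_metrics.park_mean(c5s) if c5s else 0.0
    c6 = image_metrics.park_mean(c6s) if c6s else 0.0
    c9 = image_metrics.park_mean(c9s) if c9s else 0.0

    return {
        "C1": h_val,
        "C2": c2,
        "C3": c3,
        "C4": c4,
        "C5": c5,
        "C6": c6,
        "C7": c7,
        "C8": c8,
        "C9": c9,
        "C10": c10,
        "C11": c11,
        "C12": c12,
    }


def _auto_bounds(raw: pd.DataFrame, configured: dict) -> dict:
    """Config bounds win; otherwise min-max across the run's parks.

    A constant column cannot be min-max scaled; it gets unit-width bounds
    centered on the value, normalizing every park to 0.5.
    """
    bounds = dict(configured)
    for name in aggregation.INDICATOR_NAMES:
        if name in bounds:
            continue
        col = raw[name].astype(float)
        lo, hi = col.min(), col.max()
        bounds[name] = (lo, hi) if hi > lo else (lo - 0.5, lo + 0.5)
    return bounds


def spatial_stage(config: RunConfig, scene_dir: Path, manifest: dict) -> dict:
    rows = []
    for park in manifest.get("parks", []):
        raw = _raw_indicators(config, Path(scene_dir) / park["park_id"], park)
        rows.append({"park_id": park["park_id"], **raw})
    raw_df = pd.DataFrame(rows, columns=["park_id", *aggregation.INDICATOR_NAMES])
    if raw_df.empty:
        empty = pd.DataFrame(
            columns=["park_id", "horizontal", "vertical", "three_dimensional", "overall"]
        )
        return {"indicators": raw_df, "dimension_scores": empty}
    bounds = _auto_bounds(raw_df, config.normalization_bounds)
    vectors = aggregation.normalize_indicators(raw_df, bounds)
    scores = aggregation.scores_frame(vectors)
    norm_df = pd.DataFrame(
        [{"park_id": v.park_id, **dict(zip(aggregation.INDICATOR_NAMES, v.c))} for v in vectors]
    )
    indicators = raw_df.merge(norm_df, on="park_id", suffixes=("_raw", ""))
    return {"indicators": indicators, "dimension_scores": scores}


def psych_stage(config: RunConfig, scene_dir: Path, manifest: dict) -> dict:
    ids = _park_ids(manifest)
    columns = [
        "park_id",
        "n_landscape",
        "n_park",
        "relative_evaluation_rate",
        "landscape_emotional_value",
        "park_emotional_value",
        "relative_emotional_value",
    ]
    reviews_path = Path(scene_dir) / "reviews.csv"
    if not ids or not reviews_path.exists():
        return {"summary": pd.DataFrame(columns=columns), "regression": None, "dropped": 0}
    records, dropped = read_reviews(reviews_path)
    scorer = sentiment_analysis.LexiconScorer.default()
    summaries = []
    for pid in ids:
        park_records = [r for r in records if r.park_id == pid]
        if park_records:
            summaries.append(sentiment_analysis.summarize_park(park_records, scorer))
    summary = pd.DataFrame([s.__dict__ for s in summaries], columns=columns)
    rates = {s.relative_evaluation_rate for s in summaries}
    regression = (
        sentiment_analysis.fit_rate_emotion_regression(summaries)
        if len(summaries) >= 3 and len(rates) >= 2
        else None
    )
    return {"summary": summary, "regression": regression, "dropped": dropped}


def behavior_stage(config: RunConfig, scene_dir: Path, manifest: dict) -> dict:
    rows = []
    ndig = config.rounding.get("thermal", 4)
    for park in manifest.get("parks", []):
        pdir = Path(scene_dir) / park["park_id"]
        cell = park.get("cell_size_m", config.cell_size_m)
        snapshots = []
        for i in range(park.get("n_snapshots", 0)):
            r = read_raster(pdir / f"heat_{i}.asc")
            snapshots.append(behavior_metrics.HeatSnapshot(r.values, r.mask, timestamp=f"t{i}"))
        tmean = behavior_metrics.thermal_mean(snapshots) if snapshots else np.nan
        grade = (
            behavior_metrics.thermal_grade(tmean, config.thermal_thresholds)
            if snapshots
            else ""
        )
        pts = pd.read_csv(pdir / "visitors.csv")[["x_m", "y_m"]].to_numpy()
        nrows_, ncols_ = read_raster(pdir / "dem.asc").shape
        area = nrows_ * ncols_ * cell**2
        visitors = behavior_metrics.VisitorPointSet(points=pts, park_area_m2=area)
        surface = behavior_metrics.kernel_density(
            visitors,
            bandwidth_m=config.kde_bandwidth_m,
            extent=(0.0, ncols_ * cell, 0.0, nrows_ * cell),
            cell_size_m=cell,
        )
        rows.append(
            {
                "park_id": park["park_id"],
                "thermal_mean": round_half_even(tmean, ndig) if snapshots else np.nan,
                "thermal_grade": grade,
                "mean_density": round_half_even(surface.mean_over(), max(ndig, 6)),
                "n_visitors": len(pts),
            }
        )
    summary = pd.DataFrame(
        rows, columns=["park_id", "thermal_mean", "thermal_grade", "mean_density", "n_visitors"]
    )
    if len(summary) >= 3 and summary["mean_density"].nunique() >= 3:
        summary["density_grade"] = behavior_metrics.density_grades(summary["mean_density"])
    behavior_path = Path(scene_dir) / "behavior.csv"
    obs = None
    if behavior_path.exists() and len(summary):
        df = pd.read_csv(behavior_path)
        records = [
            behavior_metrics.BehaviorRecord(
                park_id=str(r["park_id"]),
                recreation_time_h=float(r["recreation_time_h"]),
                recreation_number=int(r["recreation_number"]),
                recreation_frequency=float(r["recreation_frequency"]),
                purposes=tuple(str(r["purposes"]).split(";")) if r["purposes"] else (),
            )
            for _, r in df.iterrows()
        ]
        obs = behavior_metrics.behavior_summary(records)
    return {"summary": summary, "observation": obs}


def couple_stage(config: RunConfig, spatial: dict, psych: dict, behavior: dict) -> pd.DataFrame:
    cols = [
        "park_id",
        "coupling_index",
        "coordination_index",
        "coupling_coordination_index",
        "level",
        "label",
    ]
    scores = spatial["dimension_scores"]
    senti = psych["summary"]
    behav = behavior["summary"]
    if len(scores) < 2 or len(senti) < 2 or len(behav) < 2:
        return pd.DataFrame(columns=cols)
    table = (
        scores[["park_id", "overall"]]
        .merge(senti[["park_id", "relative_emotional_value"]], on="park_id")
        .merge(behav[["park_id", "thermal_mean", "mean_density"]], on="park_id")
    )
    if len(table) < 2:
        return pd.DataFrame(columns=cols)

    # behavioral composite: mean of the min-max scaled thermal and density
    def scaled(col):
        v = table[col].astype(float).to_numpy()
        return np.zeros_like(v) if v.max() == v.min() else (v - v.min()) / (v.max() - v.min())

    table["behavioral"] = 0.5 * (scaled("thermal_mean") + scaled("mean_density"))
    table = table.rename(
        columns={"overall": "spatial", "relative_emotional_value": "psychological"}
    )
    try:
        return coupling_model.couple_parks(
            table,
            ["spatial", "psychological", "behavioral"],
            weights=config.coupling_weights,
        )[cols]
    except ValueError:
        # a constant dimension makes scaling undefined; report no coupling
        return pd.DataFrame(columns=cols)
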