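"""Raster/table I/O, run configuration, and the pipeline driver.

Grid convention: row-major arrays, origin at the top-left corner, half-open
cell extents.  Park masks are boolean arrays of identical shape; nodata cells
are excluded from the mask and never imputed.

Supported raster formats are Esri ASCII grid (``.asc``, read/write) and
single-band GeoTIFF (``.tif``/``.tiff``, read-only, via :mod:`tifffile`).
"""

from __future__ import annotations

import dataclasses
import decimal
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Raster",
    "ParkRecord",
    "ReviewRecord",
    "RunConfig",
    "RasterFormatError",
    "PipelineError",
    "read_raster",
    "write_raster",
    "read_reviews",
    "run_pipeline",
    "round_half_even",
]

log = logging.getLogger("waterscape")

VALID_TARGETS = ("landscape", "park")


class RasterFormatError(ValueError):
    """Raised when a raster file cannot be interpreted."""


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; message names the stage."""


def round_half_even(x: float, ndigits: int) -> float:
    """Round on the decimal representation with banker's rounding.

    ``round()`` on binary floats misrounds values such as 0.59945 whose decimal
    tie is not representable; routing through :class:`decimal.Decimal` keeps
    published comparisons exact at the printed precision.
    """
    d = decimal.Decimal(repr(float(x))).quantize(
        decimal.Decimal(1).scaleb(-ndigits), rounding=decimal.ROUND_HALF_EVEN
    )
    return float(d)


@dataclass(frozen=True)
class Raster:
    """A single-band grid with cell size and validity mask."""

    values: np.ndarray
    cell_size_m: float
    mask: np.ndarray
    kind: str = "continuous"  # or "categorical"
    nodata: float | int | None = None

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise RasterFormatError(f"expected a 2-D grid, got ndim={self.values.ndim}")
        if self.mask.shape != self.values.shape:
            raise RasterFormatError("mask shape differs from value shape")
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area_m2(self) -> float:
        return self.cell_size_m**2

    def masked_values(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass(frozen=True)
class ParkRecord:
    park_id: str
    name: str
    area_ha: float
    bank: str
    category: str = ""

    def __post_init__(self) -> None:
        if self.area_ha <= 0:
            raise ValueError(f"area_ha must be positive, got {self.area_ha}")
        if self.bank not in ("north", "south"):
            raise ValueError(f"bank must be 'north' or 'south', got {self.bank!r}")


@dataclass
class ReviewRecord:
    park_id: str
    target: str
    text: str
    score: float | None = None

    def __post_init__(self) -> None:
        if self.target not in VALID_TARGETS:
            raise ValueError(f"target must be one of {VALID_TARGETS}, got {self.target!r}")
        if self.score is not None and not (0.0 <= self.score <= 10.0):
            raise ValueError(f"score must lie in [0, 10], got {self.score}")


#: Rounding decimals per output family (indices / emotional values & rates /
#: coupling quantities / thermal & density values).
DEFAULT_ROUNDING = {"index": 4, "emotion": 1, "coupling": 3, "thermal": 4}


@dataclass
class RunConfig:
    """Everything a run needs beyond the input files themselves."""

    cell_size_m: float = 15.0
    normalization_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    hemeroby_degrees: dict[int, int] = field(default_factory=dict)
    grading_k: int = 4
    thermal_thresholds: tuple[float, float] = (2.0, 5.0)
    kde_bandwidth_m: float | str = "auto"
    coupling_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    rounding: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_ROUNDING))
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.thermal_thresholds
        if not lo < hi:
            raise ValueError("thermal thresholds must be strictly increasing")
        if self.grading_k < 2:
            raise ValueError("grading_k must be >= 2")
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")
        w = self.coupling_weights
        if any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("coupling_weights must be nonnegative and sum to 1")
        if isinstance(self.kde_bandwidth_m, (int, float)) and self.kde_bandwidth_m <= 0:
            raise ValueError("kde_bandwidth_m must be positive or 'auto'")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "normalization_bounds" in raw:
            raw["normalization_bounds"] = {
                k: tuple(v) for k, v in raw["normalization_bounds"].items()
            }
        if "hemeroby_degrees" in raw:
            raw["hemeroby_degrees"] = {int(k): int(v) for k, v in raw["hemeroby_degrees"].items()}
        for key in ("thermal_thresholds", "coupling_weights"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Raster I/O
# ---------------------------------------------------------------------------

_ASC_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def read_raster(
    path: str | Path,
    kind: str = "continuous",
    cell_size_m: float | None = None,
    nodata: float | int | None = None,
) -> Raster:
    """Read a single-band raster as a :class:`Raster`.

    Esri ASCII grids carry their own cell size and nodata value; GeoTIFFs must
    be single-band and need ``cell_size_m`` supplied (the file's geokeys are
    not interpreted — inputs are assumed co-registered).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if kind not in ("categorical", "continuous"):
        raise ValueError(f"kind must be 'categorical' or 'continuous', got {kind!r}")
    suffix = path.suffix.lower()
    if suffix == ".asc":
        values, cellsize, file_nodata = _read_ascii_grid(path)
        cell = cell_size_m if cell_size_m is not None else cellsize
        nd = nodata if nodata is not None else file_nodata
    elif suffix in (".tif", ".tiff"):
        import tifffile

        values = np.asarray(tifffile.imread(path))
        if values.ndim != 2:
            raise RasterFormatError(
                f"{path.name}: expected a single-band raster, got shape {values.shape}"
            )
        values = values.astype(float)
        if cell_size_m is None:
            raise RasterFormatError(
                f"{path.name}: GeoTIFF cell size is not read from geokeys; "
                "pass cell_size_m explicitly"
            )
        cell = cell_size_m
        nd = nodata
    else:
        raise RasterFormatError(f"unsupported raster format: {path.suffix!r}")

    mask = np.isfinite(values)
    if nd is not None:
        mask &= values != nd
    if kind == "categorical":
        masked = values[mask]
        if masked.size and not np.allclose(masked, np.round(masked)):
            raise RasterFormatError(f"{path.name}: categorical raster has non-integer values")
        out = np.zeros_like(values, dtype=np.int64)
        out[mask] = np.round(values[mask]).astype(np.int64)
        values = out
    return Raster(values=values, cell_size_m=float(cell), mask=mask, kind=kind, nodata=nd)


def _read_ascii_grid(path: Path) -> tuple[np.ndarray, float, float | None]:
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not data_lines and key in _ASC_HEADER_KEYS:
                header[key] = float(parts[1])
            else:
                data_lines.append(line)
    for required in ("ncols", "nrows", "cellsize"):
        if required not in header:
            raise RasterFormatError(f"{path.name}: ASCII grid header missing '{required}'")
    values = np.loadtxt(data_lines, ndmin=2)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (nrows, ncols):
        raise RasterFormatError(
            f"{path.name}: data shape {values.shape} != header ({nrows}, {ncols})"
        )
    return values, header["cellsize"], header.get("nodata_value")


def write_raster(path: str | Path, raster: Raster) -> Path:
    """Write an Esri ASCII grid; values round-trip exactly through repr."""
    path = Path(path)
    if path.suffix.lower() != ".asc":
        raise RasterFormatError("write_raster emits Esri ASCII grids (.asc) only")
    nodata = raster.nodata if raster.nodata is not None else -9999
    values = raster.values.astype(float).copy()
    values[~raster.mask] = nodata
    nrows, ncols = raster.shape
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write(f"cellsize {raster.cell_size_m!r}\n")
        fh.write(f"nodata_value {nodata!r}\n")
        for row in values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
    return path


# ---------------------------------------------------------------------------
# Review tables
# ---------------------------------------------------------------------------


def read_reviews(path: str | Path) -> tuple[list[ReviewRecord], int]:
    """Read a review CSV; returns (records, number of empty-text rows dropped)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"park_id", "target", "text"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"reviews CSV missing columns: {sorted(missing)}")
    records: list[ReviewRecord] = []
    dropped = 0
    for idx, row in df.iterrows():
        target = row["target"]
        if target not in VALID_TARGETS:
            raise ValueError(f"row {idx}: unknown target label {target!r}")
        if not row["text"].strip():
            dropped += 1
            continue
        score = None
        if "score" in df.columns and row["score"].strip():
            score = float(row["score"])
        records.append(ReviewRecord(row["park_id"], target, row["text"], score))
    return records, dropped


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig, scene_dir: str | Path, outdir: str | Path) -> dict[str, Path]:
    """Run every stage on a scene directory and write the result bundle.

    The scene directory layout is the one produced by
    :func:`waterscape.synthetic_data.write_scene`; see that module's docs.
    Returns a mapping of output name -> written path.
    """
    from waterscape import pipeline

    scene_dir, outdir = Path(scene_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    log_lines = ["config: " + json.dumps(config.to_dict(), sort_keys=True, default=list)]

    def stage(name, func):
        try:
            return func()
        except Exception as exc:  # noqa: BLE001 - stage name is the contract
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc

    manifest = stage("manifest", lambda: pipeline.load_manifest(scene_dir))
    spatial = stage("spatial", lambda: pipeline.spatial_stage(config, scene_dir, manifest))
    psych = stage("psych", lambda: pipeline.psych_stage(config, scene_dir, manifest))
    behavior = stage("behavior", lambda: pipeline.behavior_stage(config, scene_dir, manifest))
    couple = stage(
        "couple", lambda: pipeline.couple_stage(config, spatial, psych, behavior)
    )

    frames = {
        "indicators": spatial["indicators"],
        "dimension_scores": spatial["dimension_scores"],
        "sentiment_summary": psych["summary"],
        "behavior_summary": behavior["summary"],
        "coupling": couple,
    }
    for name, frame in frames.items():
        out = outdir / f"{name}.csv"
        frame.to_csv(out, index=False, lineterminator="\n")
        outputs[name] = out
        log_lines.append(f"wrote {name}: {len(frame)} rows")
    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    outputs["log"] = outdir / "run_log.txt"
    return outputs
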