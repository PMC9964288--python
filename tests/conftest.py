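from __future__ import annotations

import numpy as np
import pytest

from waterscape.landcover_metrics import LandCoverGrid
from waterscape.synthetic_data import SceneSpec, write_scene
from waterscape.terrain_metrics import ElevationGrid


def make_landcover(codes, cell_size_m=10.0, mask=None, labels=None) -> LandCoverGrid:
    codes = np.asarray(codes, dtype=np.int64)
    if mask is None:
        mask = np.ones(codes.shape, dtype=bool)
    return LandCoverGrid(
        codes=codes,
        cell_size_m=cell_size_m,
        park_mask=np.asarray(mask, dtype=bool),
        class_labels=labels or {},
    )


def make_dem(elevation, cell_size_m=1.0, mask=None) -> ElevationGrid:
    z = np.asarray(elevation, dtype=float)
    if mask is None:
        mask = np.ones(z.shape, dtype=bool)
    return ElevationGrid(elevation_m=z, cell_size_m=cell_size_m, park_mask=np.asarray(mask, bool))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def scene_specs() -> list[SceneSpec]:
    """Three deliberately different parks for pipeline-level tests."""
    return [
        SceneSpec(
            park_id="A",
            seed=11,
            heat_spec=({"cx": 0.5, "cy": 0.5, "intensity": 7.0, "width_frac": 0.25},),
            n_visitors=120,
            landscape_value=7.0,
            park_value=4.0,
            n_landscape_reviews=30,
            canopy_height_m=(5.0, 1.0),
        ),
        SceneSpec(
            park_id="B",
            seed=22,
            relief_m=7.0,
            sky_fraction=0.4,
            landscape_value=6.0,
            park_value=5.5,
            n_visitors=60,
            heat_spec=({"cx": 0.3, "cy": 0.6, "intensity": 3.0, "width_frac": 0.15},),
            canopy_height_m=(3.0, 0.5),
        ),
        SceneSpec(
            park_id="C",
            seed=33,
            relief_m=2.0,
            sky_fraction=0.1,
            landscape_value=4.0,
            park_value=5.0,
            n_visitors=200,
            n_landscape_reviews=10,
            heat_spec=({"cx": 0.7, "cy": 0.4, "intensity": 5.0, "width_frac": 0.3},),
            canopy_height_m=(8.0, 2.0),
            class_proportions={1: 0.6, 9: 0.2, 21: 0.2},
        ),
    ]


@pytest.fixture(scope="session")
def scene_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("scene")
    write_scene(scene_specs(), out)
    return out
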