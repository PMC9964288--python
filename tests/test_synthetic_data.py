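import json

import numpy as np
import pytest

from waterscape.behavior_metrics import kernel_density, thermal_grade, thermal_mean
from waterscape.image_metrics import (
    build_layer_matrix,
    colorfulness,
    layer_superposition,
    sky_fraction,
)
from waterscape.landcover_metrics import shannon_diversity, shannon_from_proportions
from waterscape.sentiment_analysis import summarize_park
from waterscape.synthetic_data import (
    SceneSpec,
    gen_heat_and_visitors,
    gen_landcover,
    gen_panorama,
    gen_reviews,
    gen_terrain,
    vegetation_mask_of,
    write_scene,
)
from waterscape.terrain_metrics import green_volume, relief_amplitude


class TestGenLandcover:
    def test_single_class_uniform(self):
        spec = SceneSpec(class_proportions={9: 1.0}, shape=(20, 20))
        grid = gen_landcover(spec)
        assert (grid.codes == 9).all()

    def test_deterministic_per_seed(self):
        spec = SceneSpec(seed=42)
        np.testing.assert_array_equal(gen_landcover(spec).codes, gen_landcover(spec).codes)

    def test_seed_changes_grid(self):
        a = gen_landcover(SceneSpec(seed=1)).codes
        b = gen_landcover(SceneSpec(seed=2)).codes
        assert (a != b).any()

    def test_proportions_recovered_at_200(self):
        spec = SceneSpec(
            shape=(200, 200), class_proportions={1: 0.5, 5: 0.3, 9: 0.2}, seed=5
        )
        grid = gen_landcover(spec)
        for code, target in spec.class_proportions.items():
            got = (grid.codes == code).mean()
            assert got == pytest.approx(target, abs=0.02)
        h = shannon_diversity(grid)
        assert h == pytest.approx(shannon_from_proportions([0.5, 0.3, 0.2]), abs=0.02)

    def test_invalid_simplex_rejected(self):
        with pytest.raises(ValueError, match="proportions"):
            SceneSpec(class_proportions={1: 0.7, 9: 0.7})


class TestGenTerrain:
    def test_zero_relief_flat(self):
        dem, _ = gen_terrain(SceneSpec(relief_m=0.0))
        assert relief_amplitude(dem) == 0.0

    def test_relief_exact_by_construction(self):
        dem, _ = gen_terrain(SceneSpec(relief_m=7.0, seed=3))
        assert relief_amplitude(dem) == pytest.approx(7.0, abs=1e-12)

    def test_uniform_canopy_green_volume_closed_form(self):
        spec = SceneSpec(shape=(12, 12), cell_size_m=0.5, canopy_height_m=(3.0, 0.0), seed=9)
        veg = np.zeros((12, 12), dtype=bool)
        veg[:10, :10] = True
        dem, dsm = gen_terrain(spec, vegetation_mask=veg)
        assert green_volume(dsm, dem) == pytest.approx(100 * 0.25 * 3.0)

    def test_surface_at_least_ground(self):
        dem, dsm = gen_terrain(SceneSpec(seed=8, canopy_height_m=(4.0, 1.0)))
        assert (dsm.surface_m >= dem.elevation_m - 1e-9).all()


class TestGenPanorama:
    def test_sky_fraction_by_construction(self):
        pano = gen_panorama(SceneSpec(sky_fraction=0.3, pano_shape=(120, 240)))
        assert sky_fraction(pano) == pytest.approx(0.3)

    def test_single_band_superposition_one(self):
        pano = gen_panorama(SceneSpec(sky_fraction=1.0))
        assert layer_superposition(build_layer_matrix(pano)) == 1.0

    def test_grayscale_palette_zero_colorfulness(self):
        gray = {0: (128, 128, 128), 1: (90, 90, 90), 2: (40, 40, 40), 9: (200, 200, 200)}
        pano = gen_panorama(SceneSpec(sky_fraction=0.25, palette=gray))
        assert colorfulness(pano) == 0.0

    def test_labels_match_mask(self):
        pano = gen_panorama(SceneSpec(sky_fraction=0.4))
        np.testing.assert_array_equal(pano.sky_mask, pano.layer_labels == 0)


class TestGenReviews:
    def test_all_positive_landscape(self):
        spec = SceneSpec(
            n_landscape_reviews=5, n_park_reviews=5, landscape_value=10.0, park_value=10.0
        )
        records = gen_reviews(spec)
        summary = summarize_park(records)
        assert summary.landscape_emotional_value == 10.0

    def test_qcp_counts_give_published_rate(self):
        spec = SceneSpec(
            park_id="QCP",
            n_landscape_reviews=410,
            n_park_reviews=1376,
            landscape_value=6.0,
            park_value=5.0,
        )
        records = gen_reviews(spec)
        summary = summarize_park(records)
        assert summary.relative_evaluation_rate == 29.8

    def test_balanced_mix_is_neutral(self):
        spec = SceneSpec(
            n_landscape_reviews=10, n_park_reviews=20, landscape_value=5.0, park_value=5.0
        )
        summary = summarize_park(gen_reviews(spec))
        assert summary.landscape_emotional_value == 5.0
        assert summary.park_emotional_value == 5.0

    def test_target_values_recovered_exactly(self):
        spec = SceneSpec(
            n_landscape_reviews=30, n_park_reviews=60, landscape_value=7.2, park_value=4.6
        )
        summary = summarize_park(gen_reviews(spec))
        assert summary.landscape_emotional_value == 7.2
        assert summary.park_emotional_value == 4.6

    def test_unreachable_targets_rejected(self):
        spec = SceneSpec(
            n_landscape_reviews=50, n_park_reviews=60, landscape_value=0.5, park_value=9.0
        )
        with pytest.raises(ValueError, match="outside"):
            gen_reviews(spec)


class TestGenHeatAndVisitors:
    def test_flat_field_thermal_mean(self):
        spec = SceneSpec(heat_spec=(), n_snapshots=1, n_visitors=10)
        snapshots, _ = gen_heat_and_visitors(spec)
        assert thermal_mean(snapshots) == pytest.approx(1.0)

    def test_bump_peak_grades_high(self):
        hot = SceneSpec(
            heat_spec=({"cx": 0.5, "cy": 0.5, "intensity": 7.2, "width_frac": 0.6},),
            n_snapshots=1,
        )
        cold = SceneSpec(heat_spec=(), n_snapshots=1)
        hot_mean = thermal_mean(gen_heat_and_visitors(hot)[0])
        cold_mean = thermal_mean(gen_heat_and_visitors(cold)[0])
        assert thermal_grade(hot_mean) in ("sub", "high")
        assert thermal_grade(cold_mean) == "low"
        peak = gen_heat_and_visitors(hot)[0][0].values.max()
        assert thermal_grade(peak) == "high"

    def test_kde_integrates_to_visitor_count(self):
        spec = SceneSpec(n_visitors=100, seed=6)
        _, visitors = gen_heat_and_visitors(spec)
        surface = kernel_density(visitors, bandwidth_m="auto", cell_size_m=5.0)
        assert surface.integral_persons() == pytest.approx(100.0, rel=0.01)

    def test_intensity_outside_range_rejected(self):
        spec = SceneSpec(heat_spec=({"cx": 0.5, "cy": 0.5, "intensity": 9.0, "width_frac": 0.2},))
        with pytest.raises(ValueError, match="intensity"):
            gen_heat_and_visitors(spec)

    def test_deterministic(self):
        spec = SceneSpec(seed=11)
        _, v1 = gen_heat_and_visitors(spec)
        _, v2 = gen_heat_and_visitors(spec)
        np.testing.assert_array_equal(v1.points, v2.points)


class TestWriteScene:
    def test_manifest_truth_recorded(self, scene_dir):
        manifest = json.loads((scene_dir / "scene.json").read_text())
        parks = {p["park_id"]: p for p in manifest["parks"]}
        assert set(parks) == {"A", "B", "C"}
        assert parks["B"]["truth"]["relief_m"] == 7.0
        assert parks["A"]["truth"]["n_visitors"] == 120

    def test_files_exist(self, scene_dir):
        for pid in ("A", "B", "C"):
            for name in ("landcover.asc", "dem.asc", "dsm.asc", "vegmask.asc", "visitors.csv"):
                assert (scene_dir / pid / name).exists()
        assert (scene_dir / "reviews.csv").exists()
        assert (scene_dir / "behavior.csv").exists()

    def test_vegetation_mask_consistent(self, scene_dir):
        from waterscape.core_io import read_raster

        lc = read_raster(scene_dir / "A" / "landcover.asc", kind="categorical")
        veg = read_raster(scene_dir / "A" / "vegmask.asc", kind="categorical")
        from waterscape.landcover_metrics import LandCoverGrid

        grid = LandCoverGrid(codes=lc.values, cell_size_m=15.0, park_mask=lc.mask)
        np.testing.assert_array_equal(vegetation_mask_of(grid), veg.values.astype(bool))
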