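import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vinevigor import (
    GridGeoreference,
    SamplingRectangle,
    VineRecord,
    build_rectangle,
    compute_all_indices,
    compute_chm,
    mean_terrain_aspect,
    rectangle_pixels,
    zonal_statistics,
)
from vinevigor.zonal import (
    FEATURE_COLUMNS,
    FEATURE_GROUPS,
    assemble_feature_table,
    select_feature_group,
)

from conftest import make_raster


class TestRectangle:
    def test_aspect_180_gives_axis_aligned_rectangle(self):
        vine = VineRecord(1, 10.0, 20.0, 5)
        rect = build_rectangle(vine, 180.0)
        corners = rect.corners()
        assert np.ptp(corners[:, 0]) == pytest.approx(1.0)  # east-west width
        assert np.ptp(corners[:, 1]) == pytest.approx(1.2)  # north-south length

    def test_rotation_covariance_of_corners(self):
        vine = VineRecord(1, 0.0, 0.0, 5)
        base = build_rectangle(vine, 180.0).corners()
        rotated = build_rectangle(vine, 90.0).corners()
        # rotating the 180-deg corners by 90 deg clockwise about the center
        theta = np.radians(-90.0)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        expected = base @ rot.T
        rotated_set = sorted(map(tuple, np.round(rotated, 9)))
        expected_set = sorted(map(tuple, np.round(expected, 9)))
        assert rotated_set == expected_set

    @pytest.mark.parametrize("aspect", [0, 37.5, 90, 202.5])
    def test_area_invariant_under_rotation(self, aspect):
        rect = build_rectangle(VineRecord(1, 5.0, 5.0, 5), aspect)
        assert rect.area == pytest.approx(1.2)

    def test_positive_dimensions_required(self):
        with pytest.raises(ValueError):
            SamplingRectangle((0, 0), across_row_width=0.0)


class TestRectanglePixels:
    def test_axis_aligned_count_480(self, fine_georef):
        rect = SamplingRectangle((5.0, 25.0), 1.0, 1.2, orientation_deg=0.0)
        pixels = rectangle_pixels(rect, fine_georef, (1000, 1000))
        assert len(pixels) == 480  # 20 x 24 pixel centers at 0.05 m

    def test_fully_outside_raster_empty(self, fine_georef):
        rect = SamplingRectangle((-50.0, -50.0), 1.0, 1.2, 0.0)
        assert len(rectangle_pixels(rect, fine_georef, (100, 100))) == 0

    def test_rotation_keeps_count_within_5_percent(self, fine_georef):
        base = rectangle_pixels(SamplingRectangle((5.0, 25.0), 1.0, 1.2, 0.0), fine_georef, (1000, 1000))
        rot = rectangle_pixels(SamplingRectangle((5.0, 25.0), 1.0, 1.2, 90.0), fine_georef, (1000, 1000))
        assert abs(len(rot) - len(base)) / len(base) <= 0.05


class TestZonalStatistics:
    def test_hand_example_population_variance(self, georef):
        raster = make_raster([[1.0, 2.0, 3.0]], georef)
        stats = zonal_statistics(raster, np.array([[0, 0], [0, 1], [0, 2]]))
        assert (stats.mean, stats.min, stats.max, stats.range, stats.count) == (2.0, 1.0, 3.0, 2.0, 3)
        assert stats.variance == pytest.approx(2.0 / 3.0)

    def test_empty_selection_nodata_stats(self, georef):
        stats = zonal_statistics(make_raster(np.ones((2, 2)), georef), np.empty((0, 2)))
        assert stats.count == 0 and np.isnan(stats.mean)

    def test_constant_selection(self, georef):
        raster = make_raster(np.full((3, 3), 7.0), georef)
        stats = zonal_statistics(raster, np.array([[0, 0], [1, 1]]))
        assert stats.std == 0.0 and stats.range == 0.0

    def test_mask_restricts_selection(self, georef):
        raster = make_raster([[1.0, 100.0]], georef)
        mask = make_raster([[1.0, 0.0]], georef)
        stats = zonal_statistics(raster, np.array([[0, 0], [0, 1]]), mask)
        assert stats.count == 1 and stats.mean == 1.0

    @given(st.lists(st.floats(-100, 100, allow_nan=False), min_size=1, max_size=30))
    @settings(max_examples=60, deadline=None)
    def test_internal_consistency(self, values):
        arr = np.asarray(values).reshape(1, -1)
        raster = make_raster(arr, GridGeoreference(0, 10, 1.0))
        pixels = np.column_stack([np.zeros(arr.size, int), np.arange(arr.size)])
        stats = zonal_statistics(raster, pixels)
        assert stats.min - 1e-9 <= stats.mean <= stats.max + 1e-9
        assert stats.range == pytest.approx(stats.max - stats.min)
        assert stats.variance == pytest.approx(stats.std**2, rel=1e-9, abs=1e-12)


@pytest.fixture(scope="module")
def feature_table(small_scene):
    from vinevigor.pipeline import PipelineConfig, extract_features

    cfg = PipelineConfig()
    vi, chm, tex, fused, table = extract_features(small_scene, cfg)
    return table, small_scene


class TestFeatureTable:
    def test_all_17_feature_columns_present(self, feature_table):
        table, _ = feature_table
        assert set(FEATURE_COLUMNS) <= set(table.columns)
        assert "growth_class" in table.columns

    def test_class0_vines_have_zero_volume(self, feature_table):
        table, scene = feature_table
        zero = table[table.growth_class == 0]
        assert len(zero) > 0
        assert np.all(zero.CHM_Volume == 0.0)

    def test_excluded_flag_matches_empty_intersections(self, feature_table):
        table, _ = feature_table
        assert np.array_equal(table.excluded.values, (table["count"] == 0).values)

    def test_per_class_medians_increase_with_class(self, feature_table):
        table, _ = feature_table
        included = table[~table.excluded]
        for column in ("CHM_mean", "CHM_Volume"):
            medians = included.groupby("growth_class")[column].median()
            ordered = [medians[c] for c in (1, 3, 5, 7, 9) if c in medians.index]
            assert all(b > a for a, b in zip(ordered, ordered[1:])), column

    def test_masked_count_bounded_by_rectangle_count(self, feature_table):
        table, scene = feature_table
        max_pixels = (1.0 / 0.05 + 1) * (1.2 / 0.05 + 1)
        assert table["count"].max() <= max_pixels


class TestFeatureGroups:
    @pytest.fixture()
    def table(self):
        rng = np.random.default_rng(0)
        data = {c: rng.random(10) for c in FEATURE_COLUMNS}
        data["growth_class"] = rng.choice([0, 1, 3, 5, 7, 9], 10)
        return pd.DataFrame(data)

    @pytest.mark.parametrize("group_id,size", [(1, 6), (2, 4), (3, 4), (4, 10), (5, 10), (6, 8), (7, 14)])
    def test_group_column_counts(self, table, group_id, size):
        selected = select_feature_group(table, group_id)
        assert len(selected.columns) - 1 == size  # minus growth_class

    def test_group4_is_union_of_groups_1_and_2(self, table):
        g4 = set(select_feature_group(table, 4).columns)
        g1 = set(select_feature_group(table, 1).columns)
        g2 = set(select_feature_group(table, 2).columns)
        assert g4 == g1 | g2

    def test_unknown_group_errors(self, table):
        with pytest.raises(ValueError, match="1..7"):
            select_feature_group(table, 8)


class TestAspect:
    def test_mean_aspect_recovers_plane_orientation(self, small_scene):
        aspect = mean_terrain_aspect(small_scene.dtm)
        assert aspect == pytest.approx(small_scene.config.aspect_deg, abs=1.0)
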