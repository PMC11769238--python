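import numpy as np
import pytest

from vinevigor import (
    MaskConfig,
    compute_all_indices,
    fuse_masks,
    mask_agreement,
    otsu_threshold,
    segment_objects,
    select_vine_segments,
    threshold_mask,
)

from _oracles import otsu_bruteforce
from conftest import make_raster


class TestThresholdMask:
    def test_strict_inequality_at_threshold(self):
        mask = threshold_mask(make_raster([[0.71, 0.70]]), 0.7)
        assert mask.values.tolist() == [[1.0, 0.0]]

    def test_all_below_gives_zeros(self):
        mask = threshold_mask(make_raster(np.full((3, 3), 0.2)), 0.7)
        assert not np.any(mask.values == 1)

    def test_raising_threshold_never_increases_coverage(self):
        rng = np.random.default_rng(0)
        raster = make_raster(rng.random((20, 20)))
        coverages = [(threshold_mask(raster, t).values == 1).sum() for t in np.linspace(0, 1, 11)]
        assert all(b <= a for a, b in zip(coverages, coverages[1:]))

    def test_nodata_preserved(self):
        values = np.array([[0.9, -9999.0]])
        mask = threshold_mask(make_raster(values), 0.7)
        assert mask.values[0, 1] == -9999.0


class TestOtsu:
    def test_separates_two_modes(self):
        values = np.concatenate([np.full(500, 0.2), np.full(500, 0.8)])
        t = otsu_threshold(make_raster(values.reshape(20, 50)))
        assert 0.2 < t < 0.8

    def test_achieves_bruteforce_between_class_variance(self):
        # the argmax can be a plateau (empty valley bins), so compare the
        # achieved between-class variance rather than the threshold itself
        def sigma_b(values, t):
            lo, hi = values[values <= t], values[values > t]
            return len(lo) * len(hi) * (lo.mean() - hi.mean()) ** 2

        rng = np.random.default_rng(4)
        values = np.concatenate([rng.normal(0.3, 0.05, 400), rng.normal(0.75, 0.05, 600)])
        t = otsu_threshold(make_raster(values.reshape(25, 40)))
        oracle_t = otsu_bruteforce(values)
        assert sigma_b(values, t) == pytest.approx(sigma_b(values, oracle_t), rel=1e-9)

    def test_shift_covariance_up_to_bin_width(self):
        rng = np.random.default_rng(5)
        values = np.concatenate([rng.normal(0.3, 0.03, 300), rng.normal(0.7, 0.03, 300)])
        t0 = otsu_threshold(make_raster(values.reshape(20, 30)))
        t1 = otsu_threshold(make_raster(values.reshape(20, 30) + 5.0))
        assert t1 - t0 == pytest.approx(5.0, abs=(values.max() - values.min()) / 256 * 2)

    def test_constant_raster_errors(self):
        with pytest.raises(ValueError):
            otsu_threshold(make_raster(np.full((4, 4), 0.5)))


class TestSegmentation:
    def _plateaus(self):
        values = np.full((20, 30), 0.1)
        values[:, 18:] = 0.9
        rng = np.random.default_rng(1)
        return make_raster(values + rng.normal(0, 0.002, values.shape))

    def test_two_plateaus_two_pure_clusters(self):
        raster = self._plateaus()
        config = MaskConfig(n_clusters=2)
        seg = segment_objects(raster, config)
        clusters = seg.clusters.values
        assert set(np.unique(clusters)) == {0.0, 1.0}
        assert np.all(clusters[:, :16] == 0)
        assert np.all(clusters[:, 20:] == 1)

    def test_deterministic_for_fixed_seed(self):
        raster = self._plateaus()
        config = MaskConfig(n_clusters=2)
        a = segment_objects(raster, config)
        b = segment_objects(raster, config)
        np.testing.assert_array_equal(a.clusters.values, b.clusters.values)
        np.testing.assert_array_equal(a.segments.values, b.segments.values)

    def test_too_few_segments_errors(self):
        raster = make_raster(np.full((6, 6), 0.5))
        with pytest.raises(ValueError, match="smaller"):
            segment_objects(raster, MaskConfig(n_clusters=6))


class TestSelection:
    def test_auto_selects_bright_cluster_only(self):
        raster = self._bimodal()
        seg = segment_objects(raster, MaskConfig(n_clusters=2))
        mask = select_vine_segments(seg, raster, MaskConfig(n_clusters=2, osavi_threshold=0.7))
        # plateau interiors; the 1-2 px watershed boundary can fall either way
        assert np.all(mask.values[:, 14:] == 1)
        assert np.all(mask.values[:, :10] == 0)

    def test_fallback_returns_top_cluster_when_none_qualify(self):
        raster = self._bimodal(lo=0.1, hi=0.4)
        seg = segment_objects(raster, MaskConfig(n_clusters=2))
        mask = select_vine_segments(seg, raster, MaskConfig(n_clusters=2, osavi_threshold=0.7))
        assert np.any(mask.values == 1)
        assert np.all(mask.values[:, 14:] == 1)
        assert np.all(mask.values[:, :10] == 0)

    def test_manual_unknown_cluster_errors(self):
        raster = self._bimodal()
        seg = segment_objects(raster, MaskConfig(n_clusters=2))
        with pytest.raises(ValueError, match="cluster id"):
            select_vine_segments(seg, raster, MaskConfig(n_clusters=2, vine_cluster_selection=[5]))

    @staticmethod
    def _bimodal(lo=0.2, hi=0.9):
        values = np.full((15, 20), lo)
        values[:, 12:] = hi
        rng = np.random.default_rng(2)
        return make_raster(values + rng.normal(0, 0.002, values.shape))


class TestFusionAndAgreement:
    def test_truth_table_and_subset(self):
        a = make_raster([[1.0, 1.0, 0.0, 0.0]])
        b = make_raster([[1.0, 0.0, 1.0, 0.0]])
        fused = fuse_masks(a, b)
        assert fused.values.tolist() == [[1.0, 0.0, 0.0, 0.0]]
        assert (fused.values == 1).sum() <= min((a.values == 1).sum(), (b.values == 1).sum())

    def test_idempotent(self):
        m = make_raster([[1.0, 0.0], [0.0, 1.0]])
        np.testing.assert_array_equal(fuse_masks(m, m).values, m.values)

    def test_union_flag(self):
        a = make_raster([[1.0, 0.0]])
        b = make_raster([[0.0, 1.0]])
        assert fuse_masks(a, b, union=True).values.tolist() == [[1.0, 1.0]]

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            fuse_masks(make_raster(np.ones((2, 2))), make_raster(np.ones((3, 3))))

    def test_agreement_values(self):
        ref = make_raster([[1.0, 1.0, 1.0, 1.0]])
        assert mask_agreement(ref, ref) == 1.0
        half = make_raster([[1.0, 1.0, 0.0, 0.0]])
        assert mask_agreement(half, ref) == 0.5

    def test_empty_reference_errors(self):
        with pytest.raises(ValueError, match="empty"):
            mask_agreement(make_raster([[1.0]]), make_raster([[0.0]]))


class TestOnSyntheticScene:
    def test_noiseless_fused_mask_recall_at_least_09(self, noiseless_scene):
        scene = noiseless_scene
        osavi = compute_all_indices(scene.ortho)["OSAVI"]
        pixel = threshold_mask(osavi, 0.7)
        seg = segment_objects(osavi)
        obia = select_vine_segments(seg, osavi)
        fused = fuse_masks(pixel, obia)
        assert mask_agreement(fused, scene.truth_canopy) >= 0.9

    def test_default_scene_obia_precision_at_least_085(self, small_scene):
        scene = small_scene
        osavi = compute_all_indices(scene.ortho)["OSAVI"]
        seg = segment_objects(osavi)
        obia = select_vine_segments(seg, osavi)
        selected = obia.values == 1
        truth = scene.truth_canopy.values == 1
        precision = (selected & truth).sum() / selected.sum()
        assert precision >= 0.85
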