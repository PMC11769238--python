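import math

import numpy as np
import pytest

from vinevigor import GLCMConfig, quantize_band, texture_measures, texture_raster, texture_rasters, window_glcm

from _oracles import glcm_measures_bruteforce
from conftest import make_raster


class TestQuantization:
    def test_two_level_binning_with_upper_inclusive_edge(self):
        band = make_raster([[0.0, 0.5, 1.0]])
        q = quantize_band(band, GLCMConfig(levels=2, quantization_range=(0.0, 1.0)))
        assert q.values.tolist() == [[0.0, 1.0, 1.0]]

    def test_constant_band_maps_to_level_zero(self):
        q = quantize_band(make_raster(np.full((4, 4), 3.3)), GLCMConfig())
        assert np.all(q.values == 0)

    def test_monotone_ramp_yields_monotone_levels(self):
        band = make_raster(np.linspace(0, 1, 64).reshape(1, -1))
        q = quantize_band(band, GLCMConfig(levels=32))
        assert np.all(np.diff(q.values[0]) >= 0)

    def test_nodata_survives_quantization(self):
        values = np.ones((3, 3))
        values[1, 1] = -9999.0
        q = quantize_band(make_raster(values), GLCMConfig())
        assert q.values[1, 1] == -1.0


class TestWindowGLCM:
    def test_constant_patch_concentrates_on_diagonal(self):
        glcm = window_glcm(np.full((3, 3), 4), GLCMConfig(levels=8))
        assert glcm.P[4, 4] == 1.0

    def test_horizontal_stripes_all_pairs_within_rows(self):
        patch = np.array([[0, 0, 0], [1, 1, 1], [0, 0, 0]])
        glcm = window_glcm(patch, GLCMConfig(levels=2, directions=(0,)))
        assert glcm.counts.sum() == 12
        assert glcm.P[0, 0] + glcm.P[1, 1] == pytest.approx(1.0)
        assert texture_measures(glcm).con == 0.0

    def test_vertical_stripes_all_pairs_cross_levels(self):
        patch = np.array([[0, 1, 0]] * 3)
        glcm = window_glcm(patch, GLCMConfig(levels=2, directions=(0,)))
        assert glcm.counts.sum() == 12
        np.testing.assert_allclose(glcm.P, [[0.0, 0.5], [0.5, 0.0]])

    def test_pairs_touching_nodata_are_skipped(self):
        patch = np.array([[0, -1, 0]] * 3)
        glcm = window_glcm(patch, GLCMConfig(levels=2, directions=(0,)))
        assert glcm.counts.sum() == 0 and glcm.empty

    def test_matches_skimage_graycomatrix(self):
        from skimage.feature import graycomatrix

        rng = np.random.default_rng(8)
        patch = rng.integers(0, 4, size=(7, 7))
        ours = window_glcm(patch, GLCMConfig(window=7, levels=4, directions=(0,), symmetric=True))
        ref = graycomatrix(patch.astype(np.uint8), [1], [0], levels=4, symmetric=True)[:, :, 0, 0]
        np.testing.assert_array_equal(ours.counts, ref)


class TestMeasures:
    def test_constant_patch_degenerate_values(self):
        tm = texture_measures(window_glcm(np.full((3, 3), 2), GLCMConfig(levels=8)))
        assert (tm.con, tm.dis, tm.asm, tm.hom) == (0.0, 0.0, 1.0, 1.0)
        assert tm.ent == pytest.approx(0.0)
        assert math.isnan(tm.cor)

    def test_two_by_two_antidiagonal_closed_form(self):
        patch = np.array([[0, 1, 0]] * 3)
        tm = texture_measures(window_glcm(patch, GLCMConfig(levels=2, directions=(0,))))
        assert tm.con == pytest.approx(1.0)
        assert tm.dis == pytest.approx(1.0)
        assert tm.asm == pytest.approx(0.5)
        assert tm.ent == pytest.approx(math.log(2))
        assert tm.hom == pytest.approx(0.5)
        assert tm.cor == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_all_measures_match_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        patch = rng.integers(0, 4, size=(8, 8))
        cfg = GLCMConfig(window=3, levels=4)
        # the full 8x8 patch treated as one window
        glcm = window_glcm(patch, cfg)
        ours = texture_measures(glcm, cfg).as_dict()
        expected = glcm_measures_bruteforce(patch, levels=4)
        for name, value in expected.items():
            if math.isnan(value):
                assert math.isnan(ours[name])
            else:
                assert ours[name] == pytest.approx(value, abs=1e-12), name

    def test_entropy_log2_option(self):
        patch = np.array([[0, 1, 0]] * 3)
        cfg = GLCMConfig(levels=2, directions=(0,), log_base=2)
        tm = texture_measures(window_glcm(patch, cfg), cfg)
        assert tm.ent == pytest.approx(1.0)


class TestTextureRaster:
    def test_border_is_nodata_and_shape_preserved(self):
        band = make_raster(np.random.default_rng(0).random((6, 7)))
        out = texture_raster(band, "CON", GLCMConfig(levels=4))
        assert out.shape == band.shape
        assert not out.valid_mask()[0, :].any()
        assert not out.valid_mask()[:, -1].any()
        assert out.valid_mask()[1:-1, 1:-1].all()

    def test_constant_raster_interior_contrast_zero(self):
        out = texture_raster(make_raster(np.full((5, 5), 2.0)), "CON", GLCMConfig(levels=4))
        assert np.all(out.values[1:-1, 1:-1] == 0.0)

    def test_every_interior_pixel_equals_per_window_path(self):
        rng = np.random.default_rng(5)
        values = rng.random((9, 11))
        values[2, 3] = -9999.0
        band = make_raster(values)
        cfg = GLCMConfig(levels=6)
        rasters = texture_rasters(band, config=cfg)
        q = quantize_band(band, cfg).values.astype(int)
        for i in range(1, 8):
            for j in range(1, 10):
                glcm = window_glcm(q[i - 1 : i + 2, j - 1 : j + 2], cfg)
                expected = texture_measures(glcm, cfg).as_dict()
                for name, raster in rasters.items():
                    if math.isnan(expected[name]):
                        assert not raster.valid_mask()[i, j]
                    else:
                        assert raster.values[i, j] == pytest.approx(expected[name], abs=1e-12)


class TestInvariants:
    def test_normalization_and_symmetry(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            patch = rng.integers(0, 5, size=(3, 3))
            glcm = window_glcm(patch, GLCMConfig(levels=5))
            assert glcm.P.sum() == pytest.approx(1.0)
            np.testing.assert_allclose(glcm.P, glcm.P.T)

    def test_contrast_dissimilarity_transpose_invariant(self):
        rng = np.random.default_rng(10)
        patch = rng.integers(0, 4, size=(5, 5))
        cfg = GLCMConfig(window=5, levels=4, symmetric=False, directions=(0, 90))
        glcm = window_glcm(patch, cfg)
        tm = texture_measures(glcm, cfg)
        from vinevigor.texture import GLCM

        transposed = GLCM(glcm.counts.T.copy(), glcm.levels)
        tm2 = texture_measures(transposed, cfg)
        assert tm2.con == pytest.approx(tm.con)
        assert tm2.dis == pytest.approx(tm.dis)

    def test_asm_entropy_antimonotone_on_flattening_family(self):
        from vinevigor.texture import GLCM

        asms, ents = [], []
        for spread in (1, 2, 4, 8, 16):
            counts = np.zeros((16, 16), dtype=int)
            for k in range(spread):
                counts[k, k] = 1
            tm = texture_measures(GLCM(counts, 16))
            asms.append(tm.asm)
            ents.append(tm.ent)
        assert all(b < a for a, b in zip(asms, asms[1:]))
        assert all(b > a for a, b in zip(ents, ents[1:]))
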