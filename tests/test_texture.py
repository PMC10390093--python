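"""GLCM construction and Haralick features: hand-computed values, oracle
equivalence (brute-force pair enumeration and skimage on rectangles)."""

import numpy as np
import pytest
from skimage.feature import graycomatrix

from fracmorph.texture import (
    compute_glcm,
    glcm_features,
    quantize_8bit,
    region_texture,
)
from fracmorph.types import BinaryMask, DomainError, GLCM, GrayImage

from .oracles import brute_glcm


def full_mask(shape):
    return BinaryMask(np.ones(shape, dtype=bool))


class TestQuantize:
    def test_three_levels_rescaled(self):
        img = GrayImage(np.array([[10.0, 20.0, 30.0]]))
        out = quantize_8bit(img, full_mask((1, 3)))
        assert out.data.tolist() == [[0, 128, 255]]  # rounding half-up

    def test_constant_maps_to_zero(self):
        out = quantize_8bit(GrayImage(np.full((4, 4), 7.0)), full_mask((4, 4)))
        assert (out.data == 0).all()

    def test_full_range_integers_unchanged(self):
        vals = np.arange(256, dtype=float).reshape(16, 16)
        out = quantize_8bit(GrayImage(vals), full_mask((16, 16)))
        np.testing.assert_array_equal(out.data, vals.astype(np.uint8))

    def test_outside_mask_is_zero(self):
        mask = BinaryMask(np.eye(4))
        out = quantize_8bit(GrayImage(np.full((4, 4), 99.0) + np.eye(4)), mask)
        assert (out.data[~mask.data] == 0).all()


class TestComputeGLCM:
    def test_column_pattern_single_pair_type(self):
        img = GrayImage(np.array([[0, 1], [0, 1]]))
        g = compute_glcm(img, full_mask((2, 2)), offset=(0, 1), levels=2)
        assert g.matrix[0, 1] == 1.0
        assert g.matrix.sum() == 1.0

    def test_symmetric_counts_both_directions(self):
        img = GrayImage(np.array([[0, 1], [0, 1]]))
        g = compute_glcm(img, full_mask((2, 2)), offset=(0, 1), levels=2,
                         symmetric=True)
        assert g.matrix[0, 1] == 0.5
        assert g.matrix[1, 0] == 0.5

    def test_constant_image_all_mass_at_origin(self):
        img = GrayImage(np.zeros((4, 4)))
        g = compute_glcm(img, full_mask((4, 4)), levels=256)
        assert g.matrix[0, 0] == 1.0

    def test_one_pixel_mask_has_no_pairs(self):
        mask = BinaryMask(np.pad(np.ones((1, 1), dtype=bool), 2))
        with pytest.raises(DomainError):
            compute_glcm(GrayImage(np.zeros((5, 5))), mask)

    def test_masked_pairs_only(self):
        # mask splits the image into two columns; offset (0,1) pairs must
        # never straddle the unmasked middle column
        img = GrayImage(np.array([[0, 3, 1]] * 3))
        mask = BinaryMask(np.array([[1, 0, 1]] * 3, dtype=bool))
        with pytest.raises(DomainError):
            compute_glcm(img, mask, offset=(0, 1), levels=4)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(30):
            img = rng.integers(0, 8, size=(8, 8))
            mask = rng.random((8, 8)) < 0.8
            offset = (int(rng.integers(0, 2)), int(rng.integers(0, 2)))
            if offset == (0, 0):
                offset = (0, 1)
            expect = brute_glcm(img, mask, offset, levels=8)
            if expect.sum() == 0:
                continue
            got = compute_glcm(GrayImage(img), BinaryMask(mask), offset=offset,
                               levels=8)
            np.testing.assert_allclose(got.matrix, expect, atol=1e-12)

    def test_matches_skimage_on_full_rectangle(self, rng):
        img = rng.integers(0, 16, size=(12, 12)).astype(np.uint8)
        got = compute_glcm(GrayImage(img), full_mask((12, 12)), offset=(0, 1),
                           levels=16)
        ref = graycomatrix(img, distances=[1], angles=[0], levels=16,
                           symmetric=False, normed=True)[:, :, 0, 0]
        np.testing.assert_allclose(got.matrix, ref, atol=1e-12)


class TestFeatures:
    def test_degenerate_matrix(self):
        m = np.zeros((4, 4))
        m[0, 0] = 1.0
        f = glcm_features(GLCM(m, levels=4, offset=(0, 1), symmetric=False))
        assert f.asm == 1.0
        assert f.contrast == 0.0
        assert f.idm == 1.0
        assert f.entropy == 0.0
        assert np.isnan(f.correlation)

    def test_two_cell_antidiagonal(self):
        m = np.zeros((2, 2))
        m[0, 1] = m[1, 0] = 0.5
        f = glcm_features(GLCM(m, levels=2, offset=(0, 1), symmetric=True))
        assert f.asm == pytest.approx(0.5)
        assert f.contrast == pytest.approx(1.0)
        assert f.idm == pytest.approx(0.5)
        assert f.entropy == pytest.approx(np.log(2))
        assert f.correlation == pytest.approx(-1.0)

    def test_uniform_matrix_closed_forms(self):
        m = np.full((4, 4), 1 / 16)
        f = glcm_features(GLCM(m, levels=4, offset=(0, 1), symmetric=False))
        assert f.asm == pytest.approx(1 / 16)
        assert f.entropy == pytest.approx(np.log(16))
        assert f.correlation == pytest.approx(0.0, abs=1e-12)

    def test_entropy_maximal_for_uniform(self, rng):
        L = 6
        uniform = np.full((L, L), 1 / L ** 2)
        max_entropy = glcm_features(
            GLCM(uniform, levels=L, offset=(0, 1), symmetric=False)).entropy
        for _ in range(20):
            m = rng.random((L, L))
            m /= m.sum()
            ent = glcm_features(
                GLCM(m, levels=L, offset=(0, 1), symmetric=False)).entropy
            assert ent <= max_entropy + 1e-12

    def test_ranges_on_random_matrices(self, rng):
        for _ in range(25):
            m = rng.random((8, 8))
            m /= m.sum()
            f = glcm_features(GLCM(m, levels=8, offset=(0, 1), symmetric=False))
            assert 0 < f.asm <= 1
            assert 0 < f.idm <= 1
            assert f.contrast >= 0
            assert f.entropy >= 0
            assert -1 <= f.correlation <= 1


class TestRegionTexture:
    def test_constant_region_flat_features(self):
        mask = BinaryMask(np.pad(np.ones((6, 6), dtype=bool), 2))
        img = GrayImage(np.where(mask.data, 37.0, 0.0))
        f = region_texture(img, mask)
        assert f.contrast == 0.0
        assert f.asm == 1.0

    def test_empty_region_yields_missing_record(self):
        f = region_texture(GrayImage(np.zeros((8, 8))),
                           BinaryMask(np.zeros((8, 8), dtype=bool)))
        assert all(np.isnan(v) for v in f.as_dict().values())

    def test_contrast_feature_increases_with_contrast_level(self, tumor_mask):
        from fracmorph.synthetic import gen_textured_region
        lo = region_texture(gen_textured_region(tumor_mask, 0.5, 0.0, seed=11),
                            tumor_mask)
        hi = region_texture(gen_textured_region(tumor_mask, 5.0, 0.0, seed=11),
                            tumor_mask)
        assert hi.contrast > lo.contrast
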