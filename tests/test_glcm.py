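"""Co-occurrence matrix construction and Haralick feature definitions."""

import numpy as np
import pytest

from oracles import glcm_counts_bruteforce, random_masked_image
from radtex.glcm import (ANGLES, GLCMatrix, compute_glcm, glcm_feature_block,
                         glcm_features)
from radtex.preprocess import QuantizationRule, QuantizedROI, quantize


def qroi_from_levels(levels, n_levels, mask=None):
    levels = np.asarray(levels, dtype=np.int64)
    if mask is None:
        mask = levels > 0
    return QuantizedROI(levels=np.where(mask, levels, 0), n_levels=n_levels,
                        mask=mask, rule=QuantizationRule("raw_range", 0, 1))


class TestComputeGLCM:
    def test_two_by_two_example_probabilities(self):
        g = compute_glcm(qroi_from_levels([[1, 1], [1, 2]], 2), d=1, theta=0)
        assert g.p[0, 0] == pytest.approx(0.5)
        assert g.p[0, 1] == pytest.approx(0.25)
        assert g.p[1, 0] == pytest.approx(0.25)
        assert g.p[1, 1] == 0.0

    def test_constant_image_puts_all_mass_at_origin(self):
        g = compute_glcm(qroi_from_levels(np.ones((3, 3), int), 4), d=1, theta=45)
        assert g.p[0, 0] == 1.0
        assert g.p.sum() == 1.0

    def test_single_pixel_mask_is_empty_flagged(self):
        g = compute_glcm(qroi_from_levels([[1]], 2), d=1, theta=0)
        assert g.empty

    def test_matches_bruteforce_enumeration_on_random_masked_images(self, rng):
        for _ in range(50):
            levels, mask, n_levels = random_masked_image(rng)
            q = qroi_from_levels(levels, n_levels, mask)
            for d in (1, 2, 3):
                for theta in ANGLES:
                    got = compute_glcm(q, d, theta)
                    counts = glcm_counts_bruteforce(levels, mask, n_levels, d, theta)
                    if counts.sum() == 0:
                        assert got.empty
                    else:
                        assert np.array_equal(got.p, counts / counts.sum())

    def test_symmetry_and_normalization_invariants(self, rng):
        for _ in range(20):
            levels, mask, n_levels = random_masked_image(rng)
            g = compute_glcm(qroi_from_levels(levels, n_levels, mask), 1, 135)
            if not g.empty:
                assert np.array_equal(g.p, g.p.T)
                assert g.p.sum() == pytest.approx(1.0, abs=1e-12)
                assert (g.p >= 0).all()

    def test_agrees_with_skimage_on_full_mask(self, rng):
        graycomatrix = pytest.importorskip("skimage.feature").graycomatrix
        img = rng.integers(0, 6, size=(10, 10)).astype(np.uint8)
        q = qroi_from_levels(img + 1, 6, mask=np.ones_like(img, bool))
        # d = 1 only: skimage rounds d*sin/cos, so its diagonal offsets at
        # d > 1 differ from the d-steps-per-axis (Chebyshev) convention here.
        # skimage's positive row offset points down, so its pi/4 is the
        # down-right diagonal — the 135-degree family here (symmetrized).
        for theta, ang in zip(ANGLES, (0, 3 * np.pi / 4, np.pi / 2, np.pi / 4)):
            ref = graycomatrix(img, [1], [ang], levels=6, symmetric=True,
                               normed=True)[:, :, 0, 0]
            got = compute_glcm(q, 1, theta)
            assert np.allclose(got.p, ref, atol=1e-12)
        for d in (2, 4):  # axis-aligned offsets are exact at any distance
            for theta, ang in ((0, 0.0), (90, np.pi / 2)):
                ref = graycomatrix(img, [d], [ang], levels=6, symmetric=True,
                                   normed=True)[:, :, 0, 0]
                assert np.allclose(compute_glcm(q, d, theta).p, ref, atol=1e-12)


class TestGLCMFeatures:
    def test_point_mass_matrix(self):
        p = np.zeros((4, 4))
        p[2, 2] = 1.0
        fv = glcm_features(GLCMatrix(p=p, d=1, theta=0, n_pairs=5))
        assert fv["GLCM_Energy"] == 1.0
        assert fv["GLCM_Entropy"] == 0.0
        assert fv["GLCM_Contrast"] == 0.0
        assert fv["GLCM_MaximumProbability"] == 1.0
        assert "GLCM_Correlation" in fv.undefined  # zero marginal variance

    def test_uniform_matrix_closed_forms(self):
        n = 8
        fv = glcm_features(GLCMatrix(p=np.full((n, n), 1 / n**2), d=1, theta=0,
                                     n_pairs=99))
        assert fv["GLCM_Entropy"] == pytest.approx(2 * np.log2(n), abs=1e-10)
        assert fv["GLCM_Energy"] == pytest.approx(1 / n**2, abs=1e-12)

    def test_hand_evaluated_contrast_and_dissimilarity(self):
        g = compute_glcm(qroi_from_levels([[1, 1], [1, 2]], 2), d=1, theta=0)
        fv = glcm_features(g)
        assert fv["GLCM_Contrast"] == pytest.approx(0.5)
        assert fv["GLCM_Dissimilarity"] == pytest.approx(0.5)

    def test_sum_average_is_twice_marginal_mean(self, rng):
        for _ in range(20):
            levels, mask, n_levels = random_masked_image(rng)
            g = compute_glcm(qroi_from_levels(levels, n_levels, mask), 1, 0)
            if g.empty:
                continue
            fv = glcm_features(g)
            px = g.p.sum(axis=1)
            mean = (np.arange(1, n_levels + 1) * px).sum()
            assert fv["GLCM_SumAverage"] == pytest.approx(2 * mean, rel=1e-10)

    def test_features_match_direct_summation_oracle(self, rng):
        levels, mask, n_levels = random_masked_image(rng, max_side=10)
        g = compute_glcm(qroi_from_levels(levels, n_levels, mask), 1, 90)
        fv = glcm_features(g)
        n = g.p.shape[0]
        auto = contrast = entropy = 0.0
        for i in range(n):
            for j in range(n):
                pij = g.p[i, j]
                auto += (i + 1) * (j + 1) * pij
                contrast += (i - j) ** 2 * pij
                if pij > 0:
                    entropy -= pij * np.log2(pij)
        assert fv["GLCM_Autocorrelation"] == pytest.approx(auto, rel=1e-12)
        assert fv["GLCM_Contrast"] == pytest.approx(contrast, rel=1e-12)
        assert fv["GLCM_Entropy"] == pytest.approx(entropy, rel=1e-12)

    def test_empty_matrix_flags_all_features(self):
        fv = glcm_features(GLCMatrix(p=np.zeros((3, 3)), d=1, theta=0, n_pairs=0))
        assert len(fv.undefined) == len(fv) == 22


class TestGLCMBlock:
    def test_block_emits_440_uniquely_named_features(self, make_roi, rng):
        q = quantize(make_roi(rng.random((8, 8))), n_levels=8)
        block = glcm_feature_block(q)
        assert len(block) == 440
        assert len(set(block.names)) == 440

    def test_90_degree_symmetric_image_matches_across_angles(self, make_roi):
        img = np.add.outer(np.abs(np.arange(-3, 4)), np.abs(np.arange(-3, 4)))
        q = quantize(make_roi(img.astype(float)), n_levels=4)
        block = glcm_feature_block(q)
        for stat in ("Contrast", "Entropy", "Correlation"):
            assert block[f"GLCM_{stat}_d1_a000"] == pytest.approx(
                block[f"GLCM_{stat}_d1_a090"], rel=1e-10)

    def test_180_degree_rotation_leaves_block_unchanged(self, make_roi, rng):
        values = rng.random((9, 9))
        q1 = quantize(make_roi(values), n_levels=8)
        q2 = quantize(make_roi(values[::-1, ::-1]), n_levels=8)
        b1, b2 = glcm_feature_block(q1), glcm_feature_block(q2)
        for name in b1.names:
            assert b1[name] == pytest.approx(b2[name], rel=1e-10), name

    def test_affine_intensity_map_leaves_block_unchanged(self, make_roi, rng):
        values = rng.random((8, 8))
        b1 = glcm_feature_block(quantize(make_roi(values), n_levels=8))
        b2 = glcm_feature_block(quantize(make_roi(5.0 * values - 2.0), n_levels=8))
        for name in b1.names:
            assert b1[name] == b2[name], name
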