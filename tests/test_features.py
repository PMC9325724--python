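"""Texture, first-order, morphological and wavelet feature correctness."""

import numpy as np
import pytest

from fetalrad.errors import DegenerateROIError
from fetalrad.features import (
    extract_all,
    family_counts,
    catalog_names,
    default_catalog,
    firstorder_features,
    glcm_features,
    glcm_matrix,
    glrlm_features,
    glrlm_matrix,
    morphological_features,
    ngtdm_features,
    ngtdm_table,
    wavelet_subbands,
)
from fetalrad.features.glrlm import RUN_DIRECTIONS, glrlm_features_single
from fetalrad.imaging import GreyImage, ROIMask, quantize

from .conftest import make_patch
from .oracles import glcm_brute, glrlm_brute, ngtdm_brute


class TestGLCM:
    def test_two_row_patch_hand_enumerated(self):
        # [[1,1],[2,2]] at 0 deg: pairs (1,1) and (2,2) only -> diag(0.5, 0.5)
        p = make_patch([[1, 1], [2, 2]], n_levels=2)
        g = glcm_matrix(p, distance=1, angles=((0, 1),))
        assert np.allclose(g, np.diag([0.5, 0.5]))

    def test_constant_patch_single_entry(self):
        p = make_patch(np.ones((4, 4), int), n_levels=1)
        g = glcm_matrix(p)
        assert g.shape == (1, 1) and g[0, 0] == 1.0

    def test_checkerboard_zero_diagonal(self):
        board = (np.indices((6, 6)).sum(axis=0) % 2) + 1
        g = glcm_matrix(make_patch(board, n_levels=2), angles=((0, 1),))
        assert np.allclose(np.diag(g), 0.0)

    def test_matches_bruteforce_on_random_patches(self, random_patches):
        for patch in random_patches:
            for d in (1, 2):
                got = glcm_matrix(patch, distance=d)
                want = glcm_brute(patch.levels, patch.mask, patch.n_levels, distance=d)
                assert np.allclose(got, want, atol=1e-12)

    def test_feature_hand_values(self):
        g = np.diag([0.5, 0.5])
        f = glcm_features(g)
        assert f["Mean of contrast"] == pytest.approx(0.0)
        assert f["Mean of covariance"] == pytest.approx(0.25)
        f_uniform = glcm_features(np.full((2, 2), 0.25))
        assert f_uniform["Mean of contrast"] == pytest.approx(0.5)

    def test_constant_patch_zero_contrast_covariance(self):
        g = glcm_matrix(make_patch(np.ones((4, 4), int), n_levels=1))
        f = glcm_features(g)
        assert f["Mean of contrast"] == 0.0
        assert f["Mean of covariance"] == 0.0

    def test_rotation_invariance_direction_average(self, random_patches):
        for patch in random_patches[:10]:
            if not patch.mask.all():
                continue
            rot = make_patch(np.rot90(patch.levels), n_levels=patch.n_levels)
            f1 = glcm_features(glcm_matrix(patch))
            f2 = glcm_features(glcm_matrix(rot))
            for k in f1:
                assert f1[k] == pytest.approx(f2[k], abs=1e-9), k


class TestGLRLM:
    def test_constant_patch_four_full_runs(self):
        p = make_patch(np.ones((4, 4), int), n_levels=1)
        m = glrlm_matrix(p, directions=((0, 1),))[0]
        assert m[0, 3] == 4 and m.sum() == 4

    def test_half_and_half_rows(self):
        p = make_patch(np.tile([1, 1, 2, 2], (4, 1)), n_levels=2)
        m = glrlm_matrix(p, directions=((0, 1),))[0]
        assert m[0, 1] == 4 and m[1, 1] == 4 and m.sum() == 8

    def test_single_column_mask_unit_runs(self):
        levels = np.ones((5, 5), int)
        mask = np.zeros((5, 5), bool)
        mask[:, 2] = True
        p = make_patch(levels, n_levels=1, mask=mask)
        m = glrlm_matrix(p, directions=((0, 1),))[0]
        assert m[0, 0] == 5  # each masked pixel its own horizontal run

    @pytest.mark.parametrize("direction", RUN_DIRECTIONS)
    def test_matches_bruteforce_per_direction(self, random_patches, direction):
        for patch in random_patches:
            got = glrlm_matrix(patch, directions=(direction,))[0]
            want = glrlm_brute(patch.levels, patch.mask, patch.n_levels, direction)
            assert np.allclose(got, want)

    def test_feature_hand_values(self):
        # single run at level 3, length 2 -> SRHGE = 9/4
        counts = np.zeros((3, 4))
        counts[2, 1] = 1
        f = glrlm_features_single(counts)
        assert f["Short-run high grey-level emphasis"] == pytest.approx(9 / 4)
        assert f["Run-length variance"] == 0.0
        assert f["Grey-level variance"] == 0.0


class TestNGTDM:
    def test_constant_patch_flat(self):
        p = make_patch(np.ones((4, 4), int), n_levels=1)
        s, n = ngtdm_table(p)
        assert np.all(s == 0) and n.sum() == 16
        f = ngtdm_features(p)
        assert f["Busyness"] == 0.0

    def test_center_ring_hand_enumeration(self):
        p = make_patch([[1, 1, 1], [1, 2, 1], [1, 1, 1]], n_levels=2)
        s, n = ngtdm_table(p)
        assert s[1] == pytest.approx(1.0)  # center differs from ring mean by 1
        s_b, n_b = ngtdm_brute(p.levels, p.mask, 2)
        assert np.allclose(s, s_b) and np.allclose(n, n_b)

    def test_matches_bruteforce_on_random_patches(self, random_patches):
        for patch in random_patches:
            s, n = ngtdm_table(patch)
            s_b, n_b = ngtdm_brute(patch.levels, patch.mask, patch.n_levels)
            assert np.allclose(s, s_b, atol=1e-9) and np.allclose(n, n_b)

    def test_level_spread_increases_complexity(self):
        base = np.tile([1, 2], (6, 3))
        spread = np.where(base == 2, 3, 1)
        c1 = ngtdm_features(make_patch(base, n_levels=3))["Complexity"]
        c2 = ngtdm_features(make_patch(spread, n_levels=3))["Complexity"]
        assert c2 > c1


class TestFirstOrder:
    def test_symmetric_three_values(self):
        f = firstorder_features(np.array([1.0, 2.0, 3.0]))
        assert f["Mean"] == 2.0
        assert f["Variance"] == pytest.approx(2 / 3)
        assert f["Skewness"] == pytest.approx(0.0)

    def test_energy_and_degenerate_sd(self):
        assert firstorder_features(np.array([1, 1, 1, 5.0]))["Energy"] == 28.0
        f = firstorder_features(np.array([2.0, 2, 2, 2]))
        assert f["Skewness"] == 0.0 and f["Standard deviation"] == 0.0


class TestMorphology:
    def test_square_geometry(self):
        m = np.zeros((64, 64), bool)
        m[10:50, 10:50] = True
        f = morphological_features(m)
        assert f["Area"] == 1600.0
        assert f["Extent"] == pytest.approx(1.0)

    def test_elongated_rectangle_more_eccentric(self):
        sq = np.zeros((80, 80), bool)
        sq[20:50, 20:50] = True
        rect = np.zeros((80, 120), bool)
        rect[30:40, 10:100] = True  # same area 900, elongated
        assert (
            morphological_features(rect)["Eccentricity"]
            > morphological_features(sq)["Eccentricity"]
        )

    def test_disk_circularity_near_one(self):
        yy, xx = np.mgrid[:60, :60]
        disk = (yy - 30) ** 2 + (xx - 30) ** 2 <= 20**2
        f = morphological_features(disk)
        assert 0.9 <= f["Circularity"] <= 1.1


class TestWavelet:
    def test_constant_image_no_detail(self):
        img = np.full((32, 32), 120.0)
        bands = wavelet_subbands(img, np.ones((32, 32), bool))
        for band in ("horizontal", "vertical", "diagonal"):
            assert np.allclose(bands[band][0], 0.0)

    def test_vertical_stripes_energy_in_one_detail_band(self):
        img = np.tile([0.0, 100.0], (32, 16))  # vertical stripes, period 2
        bands = wavelet_subbands(img, np.ones((32, 32), bool))
        e = {b: float((bands[b][0] ** 2).sum()) for b in bands}
        assert e["vertical"] > 100 * (e["horizontal"] + e["diagonal"] + 1e-12)

    def test_parseval_energy_conservation(self, rng):
        img = rng.random((40, 40)) * 255
        bands = wavelet_subbands(img, np.ones((40, 40), bool))
        total = sum(float((coeffs**2).sum()) for coeffs, _ in bands.values())
        assert total == pytest.approx(float((img**2).sum()), rel=1e-6)

    def test_too_small_bbox_raises(self):
        m = np.zeros((64, 64), bool)
        m[5:11, 5:30] = True  # 6-row bounding box
        with pytest.raises(DegenerateROIError):
            wavelet_subbands(np.zeros((64, 64)), m)


class TestCatalogAndExtraction:
    def test_catalog_counts_and_uniqueness(self):
        counts = family_counts()
        assert counts == {"morphological": 15, "texture": 73, "wavelet": 342}
        names = catalog_names()
        assert len(names) == 430 == len(set(names))

    def test_extract_all_shape_and_determinism(self, rng):
        from fetalrad.synthetic import CohortConfig, generate_cohort

        case = generate_cohort(CohortConfig(n_cases=1, seed=5, image_size=(96, 96)))[0]
        v1 = extract_all(case.image, case.mask_freehand_A)
        v2 = extract_all(case.image, case.mask_freehand_A)
        assert list(v1) == catalog_names()
        assert v1 == v2
        assert all(np.isfinite(list(v1.values())))

    def test_shift_invariance_of_matrix_features(self, rng):
        """Adding a constant before quantization leaves matrix features
        unchanged (min-max binning absorbs shifts)."""
        img = (rng.random((64, 64)) * 200).astype(float)
        mask = np.ones((64, 64), bool)
        p1 = quantize(img, mask, 16)
        p2 = quantize(img + 37.0, mask, 16)
        f1 = glcm_features(glcm_matrix(p1))
        f2 = glcm_features(glcm_matrix(p2))
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], abs=1e-9)
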