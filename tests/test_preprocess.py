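"""Normalization arms, nearest-neighbor resize/resample, ROI construction."""

import numpy as np
import pytest
from scipy import stats

from nephrotex.preprocess import (PreprocessError, PreprocessSetting,
                                  noncystic_mask, preprocess_case,
                                  reference_normalize, resample_to_spacing,
                                  resize_to_matrix, zscore_normalize)


class TestZScore:
    def test_pixel_value_against_hand_formula(self):
        img = np.full((10, 10), 100.0)
        img[0, :5] = 90.0
        img[0, 5:] = 110.0
        mu, sigma = img.mean(), img.std()
        out = zscore_normalize(img)
        assert out[0, 9] == pytest.approx((110.0 - mu) / sigma)

    def test_moments_after_normalization(self):
        rng = np.random.default_rng(7)
        out = zscore_normalize(rng.normal(40, 9, size=(64, 64)))
        assert abs(out.mean()) < 1e-9
        assert abs(out.std() - 1.0) < 1e-9

    def test_constant_image_rejected(self):
        with pytest.raises(PreprocessError):
            zscore_normalize(np.ones((8, 8)))


class TestReferenceNormalize:
    def test_reference_roi_hits_mean_100_sd_10(self):
        rng = np.random.default_rng(3)
        img = rng.normal(500, 120, size=(50, 50))
        mask = np.zeros((50, 50), bool)
        mask[10:20, 30:45] = True
        out = reference_normalize(img, mask)
        assert out[mask].mean() == pytest.approx(100.0, abs=1e-9)
        assert out[mask].std() == pytest.approx(10.0, abs=1e-9)

    def test_identity_when_already_standardized(self):
        rng = np.random.default_rng(5)
        img = rng.normal(0, 1, size=(30, 30))
        mask = np.zeros((30, 30), bool)
        mask[5:15, 5:15] = True
        v = img[mask]
        img2 = (img - v.mean()) / v.std() * 10 + 100  # ref ROI at (100, 10)
        out = reference_normalize(img2, mask)
        np.testing.assert_allclose(out, img2, atol=1e-9)

    def test_idempotent(self):
        rng = np.random.default_rng(8)
        img = rng.normal(80, 22, size=(40, 40))
        mask = rng.random((40, 40)) < 0.2
        once = reference_normalize(img, mask)
        twice = reference_normalize(once, mask)
        np.testing.assert_allclose(twice, once, atol=1e-9)

    def test_empty_mask_and_constant_roi_rejected(self):
        img = np.arange(16.0).reshape(4, 4)
        with pytest.raises(PreprocessError):
            reference_normalize(img, np.zeros((4, 4), bool))
        mask = np.zeros((4, 4), bool)
        mask[0, 0] = True  # single pixel -> zero SD
        with pytest.raises(PreprocessError):
            reference_normalize(img, mask)


class TestResize:
    def test_identity_when_already_target(self):
        img = np.random.default_rng(0).random((256, 256))
        np.testing.assert_array_equal(resize_to_matrix(img, 256), img)

    def test_masks_stay_binary(self):
        rng = np.random.default_rng(1)
        mask = rng.random((512, 512)) < 0.5
        out = resize_to_matrix(mask, 256, is_mask=True)
        assert out.dtype == bool
        assert set(np.unique(out.astype(int))) <= {0, 1}

    def test_checkerboard_downsample_hand_oracle(self):
        """4x4 -> 2x2: each output pixel takes the source pixel nearest its
        center; at the exact tie the lower index wins, so indices (0, 2)."""
        board = np.arange(16).reshape(4, 4)
        out = resize_to_matrix(board, 2)
        np.testing.assert_array_equal(out, board[np.ix_([0, 2], [0, 2])])


class TestResample:
    def test_identity_at_same_spacing(self):
        img = np.random.default_rng(2).random((100, 100))
        out, sp = resample_to_spacing(img, 1.0, 1.0)
        np.testing.assert_array_equal(out, img)
        assert sp == 1.0

    def test_extent_arithmetic(self):
        img = np.zeros((200, 200))
        out, sp = resample_to_spacing(img, 1.0, 2.0)
        assert out.shape == (100, 100)
        assert sp == 2.0

    def test_mask_area_preserved_within_boundary_error(self):
        rng = np.random.default_rng(4)
        mask = np.zeros((120, 120), bool)
        mask[20:90, 30:100] = True
        area_before = mask.sum() * 1.0**2
        out, sp = resample_to_spacing(mask, 1.0, 2.0, is_mask=True)
        area_after = out.sum() * sp**2
        # one pixel-row of boundary at the new spacing
        perimeter_px = 2 * (70 + 70) / sp
        assert abs(area_after - area_before) <= perimeter_px * sp**2

    def test_missing_spacing_rejected(self):
        with pytest.raises(PreprocessError):
            resample_to_spacing(np.zeros((4, 4)), 0.0, 1.0)


class TestNoncysticMask:
    def test_empty_cysts_returns_kidney(self):
        k = np.zeros((10, 10), bool)
        k[2:8, 2:8] = True
        out = noncystic_mask(k, np.zeros_like(k))
        np.testing.assert_array_equal(out, k)

    def test_full_overlap_is_error(self):
        k = np.ones((5, 5), bool)
        with pytest.raises(PreprocessError):
            noncystic_mask(k, k)

    def test_pixel_counting(self):
        rng = np.random.default_rng(9)
        k = rng.random((30, 30)) < 0.6
        c = rng.random((30, 30)) < 0.3
        k[0, 0], c[0, 0] = True, False  # keep result nonempty
        out = noncystic_mask(k, c)
        assert out.sum() == k.sum() - (k & c).sum()


class TestAffineInvariance:
    def test_normalizations_preserve_correlation(self, fast_case):
        img = fast_case.image
        roi = fast_case.noncystic_mask
        for out in (zscore_normalize(img),
                    reference_normalize(img, fast_case.psoas_mask)):
            r = np.corrcoef(img[roi], out[roi])[0, 1]
            assert r == pytest.approx(1.0, abs=1e-12)

    def test_skewness_kurtosis_identical_across_arms(self, fast_case):
        """First-order shape statistics are affine-invariant, hence equal
        across the three normalization arms."""
        roi = fast_case.noncystic_mask
        arms = {
            "original": fast_case.image,
            "zscore": zscore_normalize(fast_case.image),
            "reference": reference_normalize(fast_case.image,
                                             fast_case.psoas_mask),
        }
        sk = {k: stats.skew(v[roi]) for k, v in arms.items()}
        ku = {k: stats.kurtosis(v[roi]) for k, v in arms.items()}
        for k in ("zscore", "reference"):
            assert sk[k] == pytest.approx(sk["original"], abs=1e-9)
            assert ku[k] == pytest.approx(ku["original"], abs=1e-9)


def test_preprocess_case_grid_and_spacing(fast_case):
    setting = PreprocessSetting("zscore", "down_2.0mm", 32)
    img, masks, spacing = preprocess_case(fast_case, setting)
    assert spacing == 2.0
    extent_mm = fast_case.image.shape[0] * fast_case.pixel_spacing
    assert img.shape[0] == round(extent_mm / 2.0)
    assert masks["kidney"].dtype == bool
    setting_up = PreprocessSetting("original", "up_1.0mm", 8)
    img_up, _, sp_up = preprocess_case(fast_case, setting_up)
    assert sp_up == 1.0
    assert img_up.shape[0] == round(extent_mm / 1.0)


def test_setting_validation():
    with pytest.raises(PreprocessError):
        PreprocessSetting("histogram", "up_1.0mm", 32)
    with pytest.raises(PreprocessError):
        PreprocessSetting("zscore", "native", 32)
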