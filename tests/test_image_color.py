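"""Calibration, Lab sampling, HSB segmentation, areas and condition index."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage import color as skcolor

from cichlidcolor.image_color import (
    CalibrationError,
    ColorThresholds,
    FEMALE_THRESHOLDS,
    MALE_THRESHOLDS,
    calibrate_white,
    colored_area,
    condition_index,
    hsb_mask,
    lab_chromaticity,
    measure_photo,
    relative_colored_area,
    sample_belly,
)
from cichlidcolor.synthetic_data import ImageGroundTruth, dim_image, gen_fish_image


class TestLabChromaticity:
    @pytest.mark.parametrize(
        "a,b,expected", [(0, 0, 0), (20, 21, 29), (-3, 4, 5), (3, -4, 5)]
    )
    def test_known_values(self, a, b, expected):
        assert lab_chromaticity(a, b) == pytest.approx(expected)

    @given(
        a=st.floats(-120, 120, allow_nan=False),
        b=st.floats(-120, 120, allow_nan=False),
    )
    @settings(deadline=None, max_examples=200)
    def test_matches_euclidean_norm_and_sign_invariance(self, a, b):
        lc = lab_chromaticity(a, b)
        assert lc == pytest.approx(np.sqrt(a * a + b * b))
        assert lc == lab_chromaticity(-a, b) == lab_chromaticity(a, -b)

    def test_independent_of_lightness(self):
        # LC uses only a and b; round-trip in-gamut pixels at several L
        for L in (40.0, 55.0, 70.0):
            rgb = skcolor.lab2rgb(np.array([[[L, 8.0, 12.0]]]))
            lab = skcolor.rgb2lab(rgb)[0, 0]
            assert lab_chromaticity(lab[1], lab[2]) == pytest.approx(
                lab_chromaticity(8.0, 12.0), abs=0.5
            )


class TestCalibration:
    def _image_with_patch(self, value):
        img = np.full((50, 50, 3), 0.4)
        img[5:15, 5:15] = value
        return img

    def test_patch_at_reference_is_fixed_point(self):
        img = self._image_with_patch(243 / 255)
        out = calibrate_white(img, (5, 15, 5, 15), (243, 243, 243))
        assert np.allclose(out, img, atol=1e-9)

    def test_half_reference_doubles_linear_values(self):
        from cichlidcolor.image_color import linear_to_srgb, srgb_to_linear

        ref_lin = srgb_to_linear(0.8)
        half = linear_to_srgb(ref_lin / 2)
        img = self._image_with_patch(half)
        out = calibrate_white(img, (5, 15, 5, 15), (0.8, 0.8, 0.8))
        # pre-clip linear gain of exactly 2
        assert np.allclose(
            srgb_to_linear(out[20, 20]), 2 * srgb_to_linear(img[20, 20]), rtol=1e-9
        )

    def test_zero_channel_raises(self):
        img = self._image_with_patch(0.0)
        with pytest.raises(CalibrationError):
            calibrate_white(img, (5, 15, 5, 15))

    def test_dim_and_recalibrate_recovers_belly_lab(self):
        fish = gen_fish_image(ImageGroundTruth(seed=7))
        dimmed = dim_image(fish.image, 0.7)
        ref = measure_photo(
            fish.image, fish.body_mask, fish.belly_mask, 40.0,
            white_patch_region=fish.white_patch_region,
        )
        rec = measure_photo(
            dimmed, fish.body_mask, fish.belly_mask, 40.0,
            white_patch_region=fish.white_patch_region,
        )
        de = np.sqrt(
            (ref["L_mean"] - rec["L_mean"]) ** 2
            + (ref["a_mean"] - rec["a_mean"]) ** 2
            + (ref["b_mean"] - rec["b_mean"]) ** 2
        )
        assert de < 2.0


class TestSampleBelly:
    def test_uniform_patch_all_samples_equal(self):
        gt = ImageGroundTruth(noise_sd=0.0, seed=1)
        fish = gen_fish_image(gt)
        samples, mean_lc = sample_belly(fish.image, fish.belly_mask)
        lcs = [s.LC for s in samples]
        assert np.ptp(lcs) < 1e-9
        true_lc = lab_chromaticity(gt.patch_lab[1], gt.patch_lab[2])
        assert mean_lc == pytest.approx(true_lc, abs=0.5)

    def test_single_sample_matches_sixteen_on_uniform_patch(self):
        fish = gen_fish_image(ImageGroundTruth(noise_sd=0.0, seed=1))
        _, lc16 = sample_belly(fish.image, fish.belly_mask, n_samples=16)
        _, lc1 = sample_belly(fish.image, fish.belly_mask, n_samples=1)
        assert lc1 == pytest.approx(lc16, abs=1e-9)

    def test_grey_belly_is_achromatic(self):
        img = np.full((40, 60, 3), 0.5)
        mask = np.zeros((40, 60), bool)
        mask[10:30, 10:50] = True
        _, mean_lc = sample_belly(img, mask)
        assert mean_lc < 1.0

    def test_mask_too_small_raises(self):
        img = np.full((10, 10, 3), 0.5)
        mask = np.zeros((10, 10), bool)
        mask[0, :5] = True
        with pytest.raises(ValueError, match="16"):
            sample_belly(img, mask, n_samples=16)


def hsv255(rgb):
    return skcolor.rgb2hsv(np.asarray(rgb, float).reshape(1, 1, 3))[0, 0] * 255


def rgb_from_hsb255(h, s, v):
    return skcolor.hsv2rgb(np.array([[[h / 255, s / 255, v / 255]]]))[0, 0]


class TestHsbMask:
    def test_male_thresholds_include_yellow_pixel(self):
        # H=32, S=200, B=150 on the 0-255 scale
        px = rgb_from_hsb255(32, 200, 150).reshape(1, 1, 3)
        assert hsb_mask(px, MALE_THRESHOLDS)[0, 0]

    def test_male_thresholds_exclude_green_hue(self):
        px = rgb_from_hsb255(100, 200, 150).reshape(1, 1, 3)
        assert not hsb_mask(px, MALE_THRESHOLDS)[0, 0]

    def test_synthetic_patch_segmented_exactly(self):
        fish = gen_fish_image(ImageGroundTruth(noise_sd=0.0, seed=3))
        mask = hsb_mask(fish.image, MALE_THRESHOLDS)
        assert np.array_equal(mask, fish.patch_mask)

    def test_brute_force_per_pixel_agreement(self):
        rng = np.random.default_rng(0)
        img = rng.random((20, 20, 3))
        mask = hsb_mask(img, MALE_THRESHOLDS)
        t = MALE_THRESHOLDS
        for i in range(20):
            for j in range(20):
                h, s, v = hsv255(img[i, j])
                expected = (
                    t.hue_lo <= h <= t.hue_hi
                    and t.sat_lo <= s <= t.sat_hi
                    and t.bright_lo <= v <= t.bright_hi
                )
                assert mask[i, j] == expected

    def test_hue_wraparound(self):
        t = ColorThresholds(240, 10, 0, 255, 0, 255)
        red = rgb_from_hsb255(2, 200, 200).reshape(1, 1, 3)
        cyan = rgb_from_hsb255(128, 200, 200).reshape(1, 1, 3)
        assert hsb_mask(red, t)[0, 0]
        assert not hsb_mask(cyan, t)[0, 0]

    def test_widening_thresholds_is_monotone(self):
        rng = np.random.default_rng(5)
        img = rng.random((30, 30, 3))
        narrow = hsb_mask(img, ColorThresholds(10, 60, 100, 200, 80, 200))
        wide = hsb_mask(img, ColorThresholds(0, 80, 50, 255, 40, 255))
        assert np.all(wide[narrow])

    def test_invalid_threshold_range(self):
        with pytest.raises(ValueError):
            ColorThresholds(0, 64, 200, 100, 66, 255)

    def test_female_thresholds_select_purple(self):
        px = rgb_from_hsb255(200, 120, 150).reshape(1, 1, 3)
        assert hsb_mask(px, FEMALE_THRESHOLDS)[0, 0]


def brute_force_components(mask):
    """Flood-fill labeling with 8-connectivity, as an independent oracle."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    sizes = []
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            if mask[i, j] and not seen[i, j]:
                stack = [(i, j)]
                seen[i, j] = True
                size = 0
                while stack:
                    r, c = stack.pop()
                    size += 1
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (
                                0 <= rr < mask.shape[0]
                                and 0 <= cc < mask.shape[1]
                                and mask[rr, cc]
                                and not seen[rr, cc]
                            ):
                                seen[rr, cc] = True
                                stack.append((rr, cc))
                sizes.append(size)
    return sizes


class TestColoredArea:
    def blob(self, shape, rects):
        m = np.zeros(shape, bool)
        for r0, r1, c0, c1 in rects:
            m[r0:r1, c0:c1] = True
        return m

    def test_small_blob_filtered(self):
        # 0.04 cm^2 at 100 px/cm = 400 px: an 8 x 50 rectangle
        m = self.blob((60, 80), [(10, 18, 10, 60)])
        area, n = colored_area(m, px_per_cm=100.0)
        assert area == 0.0 and n == 0

    def test_large_blob_kept(self):
        # 0.10 cm^2 at 100 px/cm = 1000 px: 20 x 50
        m = self.blob((60, 80), [(10, 30, 10, 60)])
        area, n = colored_area(m, px_per_cm=100.0)
        assert area == pytest.approx(0.10) and n == 1

    def test_mixed_blobs_against_oracle(self):
        # 0.06 cm^2 (600 px) + 0.04 cm^2 (400 px), separated
        m = self.blob((100, 100), [(5, 25, 5, 35), (60, 68, 20, 70)])
        sizes = brute_force_components(m)
        assert sorted(sizes) == [400, 600]
        area, n = colored_area(m, px_per_cm=100.0)
        assert area == pytest.approx(0.06) and n == 1

    def test_diagonal_pixels_are_one_component(self):
        m = np.zeros((40, 40), bool)
        idx = np.arange(30)
        m[idx, idx] = True  # 8-connected diagonal line
        assert len(brute_force_components(m)) == 1
        area, n = colored_area(m, px_per_cm=10.0, min_component_cm2=0.05)
        assert n == 1 and area == pytest.approx(30 / 100)

    def test_random_masks_match_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            m = rng.random((50, 50)) < 0.35
            sizes = brute_force_components(m)
            px_per_cm = 10.0
            expected = sum(s for s in sizes if s / 100 > 0.05) / 100
            area, _ = colored_area(m, px_per_cm=px_per_cm)
            assert area == pytest.approx(expected)


class TestRelativeColoredArea:
    def test_simple_division(self):
        body = np.ones((30, 50), bool)  # 1500 px at 10 px/cm = 15 cm^2
        lpa, rca = relative_colored_area(1.2, body, px_per_cm=10.0)
        assert lpa == pytest.approx(15.0)
        assert rca == pytest.approx(0.08)

    def test_zero_colored_area(self):
        body = np.ones((30, 50), bool)
        _, rca = relative_colored_area(0.0, body, px_per_cm=10.0)
        assert rca == 0.0

    def test_empty_body_raises(self):
        with pytest.raises(ValueError):
            relative_colored_area(1.0, np.zeros((5, 5), bool), 10.0)

    def test_end_to_end_recovery_on_synthetic_fish(self):
        gt = ImageGroundTruth(patch_area_fraction=0.10, seed=21)
        fish = gen_fish_image(gt)
        m = measure_photo(
            fish.image, fish.body_mask, fish.belly_mask, gt.px_per_cm,
            white_patch_region=fish.white_patch_region,
        )
        assert m["RCA"] == pytest.approx(0.10, abs=0.005)


class TestConditionIndex:
    def test_direct_arithmetic(self):
        assert condition_index(5.0, 6.0) == pytest.approx(100 * 5 / 216)

    def test_linear_in_mass(self):
        assert condition_index(10.0, 6.0) == pytest.approx(2 * condition_index(5.0, 6.0))

    def test_study_scale_magnitude(self):
        # typical male: 5.728 g at 6.194 cm standard length
        assert condition_index(5.728, 6.194) == pytest.approx(2.41, abs=0.01)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            condition_index(0.0, 6.0)
        with pytest.raises(ValueError):
            condition_index(5.0, -1.0)
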