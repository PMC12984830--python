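"""Quality metrics: ROI geometry, pooled threshold, R_FAZ, CNR, SD."""

import numpy as np
import pytest

from octaquant import ImageSpec
from octaquant.metrics import FazRegion
from octaquant.quality import (RoiMask, annulus_roi, contrast_to_noise,
                               eroded_faz_roi, faz_noise_rate, noise_floor_sd,
                               pooled_noise_threshold)

SPEC = ImageSpec()


def rect_faz(h=10, w=20, at=(100, 100), shape=(512, 512)):
    mask = np.zeros(shape, bool)
    mask[at[0] : at[0] + h, at[1] : at[1] + w] = True
    return FazRegion(mask=mask, area_mm2=mask.sum() * SPEC.pixel_area_mm2)


class TestErodedFazRoi:
    def test_rectangle_erosion_matches_brute_force_disk_test(self):
        faz = rect_faz(10, 20)
        roi = eroded_faz_roi(faz, erosion_px=2).mask
        # brute force: p survives iff every pixel within Euclidean distance
        # 2 of p lies inside the rectangle
        expected = np.zeros_like(faz.mask)
        offsets = [(dr, dc) for dr in range(-2, 3) for dc in range(-2, 3)
                   if dr * dr + dc * dc <= 4]
        for r, c in np.argwhere(faz.mask):
            if all(faz.mask[r + dr, c + dc] for dr, dc in offsets):
                expected[r, c] = True
        assert np.array_equal(roi, expected)
        assert roi.sum() == 16 * 6  # 20x10 rect shrinks to 16x6 exactly

    def test_zero_erosion_is_identity(self):
        faz = rect_faz()
        roi = eroded_faz_roi(faz, erosion_px=0)
        assert np.array_equal(roi.mask, faz.mask)

    def test_tiny_faz_erosion_error(self):
        faz = rect_faz(3, 3)
        with pytest.raises(ValueError, match="erosion"):
            eroded_faz_roi(faz, erosion_px=2)

    def test_inscribed_ellipse_mode_stays_inside_faz(self):
        faz = rect_faz(40, 60, at=(200, 200))
        roi = eroded_faz_roi(faz, erosion_px=2, use_inscribed_ellipse=True)
        assert roi.mask.any()
        assert not (roi.mask & ~faz.mask).any()


class TestAnnulusRoi:
    def test_centred_annulus_area_matches_closed_form(self):
        roi = annulus_roi((1.5, 1.5), SPEC, inner_mm=0.5, outer_mm=1.5)
        area = roi.size * SPEC.pixel_area_mm2
        expected = np.pi * (1.5 ** 2 - 0.5 ** 2)  # = 2*pi
        assert abs(area - expected) / expected < 0.01

    def test_degenerate_radii_rejected(self):
        with pytest.raises(ValueError):
            annulus_roi((1.5, 1.5), SPEC, inner_mm=0.5, outer_mm=0.5)

    def test_corner_quarter_annulus(self):
        roi = annulus_roi((0.0, 0.0), SPEC, inner_mm=0.2, outer_mm=0.5)
        area = roi.size * SPEC.pixel_area_mm2
        expected = np.pi * (0.5 ** 2 - 0.2 ** 2) / 4.0
        assert abs(area - expected) / expected < 0.03

    def test_annulus_outside_field_rejected(self):
        with pytest.raises(ValueError):
            annulus_roi((50.0, 50.0), SPEC, inner_mm=0.5, outer_mm=1.5)


class TestPooledThreshold:
    def test_interpolation_rule_one_to_forty(self):
        # rank r = 0.975 * 39 = 38.025 -> between 39 and 40
        assert pooled_noise_threshold(np.arange(1, 41)) == pytest.approx(39.025)

    def test_constant_pool(self):
        assert pooled_noise_threshold(np.full(100, 7.0)) == 7.0

    def test_matches_independent_sort_oracle(self):
        pool = np.arange(1000.0)  # {0..999}
        t = pooled_noise_threshold(pool)
        s = np.sort(pool)
        r = 0.975 * (len(s) - 1)
        lo, frac = int(np.floor(r)), r - np.floor(r)
        expected = s[lo] + frac * (s[lo + 1] - s[lo])
        assert t == pytest.approx(expected)
        assert t == pytest.approx(974.025)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            pooled_noise_threshold([])

    def test_small_pool_warns(self):
        with pytest.warns(UserWarning):
            pooled_noise_threshold(np.arange(10))


class TestFazNoiseRate:
    def _roi_image(self, values, shape=(32, 32)):
        img = np.zeros(shape)
        mask = np.zeros(shape, bool)
        flat = np.asarray(values, float)
        img.flat[: flat.size] = flat
        mask.flat[: flat.size] = True
        return img, RoiMask(mask, "eroded_faz")

    def test_counting_fraction(self):
        vals = np.zeros(400)
        vals[:10] = 100.0
        img, roi = self._roi_image(vals)
        assert faz_noise_rate(img, roi, t_faz=50.0) == pytest.approx(2.5)

    def test_no_pixel_above_threshold(self):
        img, roi = self._roi_image(np.full(100, 3.0))
        assert faz_noise_rate(img, roi, t_faz=3.0) == 0.0  # strict inequality

    def test_self_consistency_with_own_percentile(self, rng):
        vals = rng.normal(50, 10, size=2000)
        img, roi = self._roi_image(vals, shape=(64, 64))
        t = pooled_noise_threshold(vals)
        rate = faz_noise_rate(img, roi, t)
        assert rate <= 2.5 + 100.0 / vals.size


class TestCnrAndNoiseFloor:
    def test_hand_computed_cnr(self):
        # ring mean 100, FAZ mean 10, FAZ sample SD exactly 5
        img = np.zeros((16, 16))
        ring = np.zeros((16, 16), bool)
        faz = np.zeros((16, 16), bool)
        ring[0, :4] = True
        img[0, :4] = 100.0
        faz[8, 0], faz[8, 1] = True, True
        d = 5.0 / np.sqrt(2.0)
        img[8, 0], img[8, 1] = 10.0 - d, 10.0 + d
        assert contrast_to_noise(img, RoiMask(ring, "annulus"), RoiMask(faz, "eroded_faz")) \
            == pytest.approx(18.0)

    def test_equal_means_give_zero_cnr(self):
        img = np.zeros((16, 16))
        ring = np.zeros((16, 16), bool); ring[0, :4] = True
        faz = np.zeros((16, 16), bool); faz[8, :4] = True
        img[0, :4] = 5.0
        img[8, :4] = [4.0, 6.0, 4.0, 6.0]
        assert contrast_to_noise(img, RoiMask(ring, "annulus"), RoiMask(faz, "eroded_faz")) \
            == pytest.approx(0.0)

    def test_constructed_roi_matches_brute_force(self):
        img = np.zeros((32, 32))
        ring = np.zeros((32, 32), bool); ring[0:2, :] = True
        faz = np.zeros((32, 32), bool); faz[10:14, 0:8] = True  # 32 px
        img[ring] = 60.0
        vals = np.tile([0.0, 10.0], 16)
        img[faz] = vals
        cnr = contrast_to_noise(img, RoiMask(ring, "annulus"), RoiMask(faz, "eroded_faz"))
        expected = (60.0 - vals.mean()) / np.std(vals, ddof=1)
        assert cnr == pytest.approx(expected)

    def test_constant_faz_cnr_undefined(self):
        img = np.zeros((16, 16))
        ring = np.zeros((16, 16), bool); ring[0, :4] = True
        faz = np.zeros((16, 16), bool); faz[8, :4] = True
        img[0, :4] = 9.0
        with pytest.raises(ValueError, match="CNR undefined"):
            contrast_to_noise(img, RoiMask(ring, "annulus"), RoiMask(faz, "eroded_faz"))

    def test_overlapping_rois_rejected(self):
        img = np.zeros((16, 16))
        m = np.zeros((16, 16), bool); m[0, :4] = True
        img[0, 0] = 1.0
        with pytest.raises(ValueError, match="disjoint"):
            contrast_to_noise(img, RoiMask(m, "annulus"), RoiMask(m, "eroded_faz"))

    def test_cnr_scale_and_offset_invariance(self, rng):
        img = rng.uniform(0, 200, (64, 64))
        ring = np.zeros((64, 64), bool); ring[:8] = True
        faz = np.zeros((64, 64), bool); faz[30:40, 30:40] = True
        base = contrast_to_noise(img, RoiMask(ring, "annulus"), RoiMask(faz, "eroded_faz"))
        scaled = contrast_to_noise(3.7 * img, RoiMask(ring, "annulus"), RoiMask(faz, "eroded_faz"))
        shifted = contrast_to_noise(img + 55.0, RoiMask(ring, "annulus"), RoiMask(faz, "eroded_faz"))
        assert scaled == pytest.approx(base)
        assert shifted == pytest.approx(base)

    def test_noise_floor_sd_examples(self):
        img = np.zeros((16, 16))
        roi = np.zeros((16, 16), bool); roi[0, 0], roi[0, 1] = True, True
        img[0, 1] = 10.0
        assert noise_floor_sd(img, RoiMask(roi, "eroded_faz")) == pytest.approx(np.sqrt(50.0))
        img[0, 1] = 0.0
        assert noise_floor_sd(img, RoiMask(roi, "eroded_faz")) == 0.0
        with pytest.raises(ValueError):
            noise_floor_sd(img, RoiMask(np.zeros((16, 16), bool), "eroded_faz"))

    def test_folded_normal_background_sd(self):
        from octaquant.synth import NoiseModel, apply_device_noise

        model = NoiseModel(background_sigma=58.0, vessel_mean=1.0)
        img = apply_device_noise(np.zeros(SPEC.shape), model, SPEC, seed=8)
        roi = np.zeros(SPEC.shape, bool)
        roi[100:300, 100:300] = True
        sd = noise_floor_sd(img, RoiMask(roi, "eroded_faz"))
        expected = 58.0 * np.sqrt(1 - 2 / np.pi)
        assert abs(sd - expected) / expected < 0.10


class TestPooledCalibration:
    def test_mean_rate_near_two_point_five_under_shared_noise(self, rng):
        # 50 ROIs drawn from one folded-normal noise law: with the pooled
        # 97.5th-percentile threshold the cohort-mean R_FAZ calibrates to
        # ~2.5% by construction
        rois = [np.abs(rng.normal(0, 58, size=900)) for _ in range(50)]
        t = pooled_noise_threshold(np.concatenate(rois))
        rates = [100.0 * (r > t).mean() for r in rois]
        assert np.mean(rates) == pytest.approx(2.5, abs=0.5)


class TestDeviceContrast:
    def test_noise_floor_sd_ordering_every_eye(self, paired):
        a, b = paired("noise_floor_sd")
        assert (b > a).all()

    def test_clean_cnr_at_least_ten_times_noisy(self, paired):
        a, b = paired("cnr")
        assert np.median(a) >= 10 * np.median(b)
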