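import numpy as np
import pytest
from skimage.draw import disk as draw_disk

from organotrack.config import AdaptiveThresholdConfig
from organotrack.fibro import (adaptive_threshold, clean_mask, extract_cohorts,
                               fibroblast_area_series, gaussian_kernel,
                               growth_rate_series)
from organotrack.io import MaskSequence


def threshold_oracle(img, k, sigma, kappa):
    """Direct per-pixel evaluation of the local threshold formula."""
    w = gaussian_kernel(k, sigma)
    pad = np.pad(img, k, mode="symmetric")
    out = np.zeros(img.shape, dtype=bool)
    for y in range(img.shape[0]):
        for x in range(img.shape[1]):
            t = np.sum(pad[y:y + 2 * k + 1, x:x + 2 * k + 1] * w)
            out[y, x] = (img[y, x] - kappa) > t
    return out


class TestAdaptiveThreshold:
    @pytest.mark.parametrize("seed", range(6))
    def test_bit_exact_against_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.uniform(0, 255, (32, 32))
        params = AdaptiveThresholdConfig(block_halfwidth=5, kappa=2.0)
        mask = adaptive_threshold(img, params)
        oracle = threshold_oracle(img, 5, params.sigma_value, 2.0)
        np.testing.assert_array_equal(mask, oracle)

    def test_constant_image_positive_kappa_all_background(self):
        img = np.full((32, 32), 100.0)
        mask = adaptive_threshold(img, AdaptiveThresholdConfig(kappa=2.0,
                                                               block_halfwidth=5))
        assert not mask.any()

    def test_bright_disc_on_flat_background(self):
        img = np.full((64, 64), 10.0)
        rr, cc = draw_disk((32, 32), 5.5)
        img[rr, cc] = 200.0
        mask = adaptive_threshold(img, AdaptiveThresholdConfig(block_halfwidth=10,
                                                               kappa=2.0))
        assert mask[32, 32]
        assert not mask[4, 4]

    def test_very_negative_kappa_all_foreground(self):
        img = np.abs(np.random.default_rng(0).uniform(1, 255, (24, 24)))
        mask = adaptive_threshold(
            img, AdaptiveThresholdConfig(block_halfwidth=5, kappa=-255.0))
        assert mask.all()

    def test_increasing_kappa_never_adds_foreground(self, rng):
        img = rng.uniform(0, 255, (24, 24))
        prev = None
        for kappa in (-5.0, 0.0, 2.0, 10.0, 50.0):
            m = adaptive_threshold(img, AdaptiveThresholdConfig(
                block_halfwidth=4, kappa=kappa))
            if prev is not None:
                assert not (m & ~prev).any()
            prev = m


def bruteforce_components(mask):
    """Flood-fill 8-connected labeling, independent of scipy."""
    mask = mask.astype(bool)
    labels = np.zeros(mask.shape, int)
    nxt = 0
    for y0 in range(mask.shape[0]):
        for x0 in range(mask.shape[1]):
            if mask[y0, x0] and labels[y0, x0] == 0:
                nxt += 1
                stack = [(y0, x0)]
                labels[y0, x0] = nxt
                while stack:
                    y, x = stack.pop()
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if (0 <= yy < mask.shape[0]
                                    and 0 <= xx < mask.shape[1]
                                    and mask[yy, xx] and labels[yy, xx] == 0):
                                labels[yy, xx] = nxt
                                stack.append((yy, xx))
    return labels, nxt


class TestCleanMask:
    def test_boundary_case_at_min_area(self):
        mask = np.zeros((40, 40), bool)
        mask[1:8, 1:8] = True          # 49 px
        mask[20:37, 20:23] = True      # 51 px
        out = clean_mask(mask, 50)
        assert not out[1:8, 1:8].any()
        assert out[20:37, 20:23].all()

    def test_empty_mask(self):
        out = clean_mask(np.zeros((8, 8), bool), 50)
        assert not out.any()

    def test_matches_bruteforce_labeling(self, rng):
        mask = rng.random((24, 24)) > 0.7
        out = clean_mask(mask, 5)
        labels, n = bruteforce_components(mask)
        expected = np.zeros_like(mask)
        for lab in range(1, n + 1):
            comp = labels == lab
            if comp.sum() >= 5:
                expected |= comp
        np.testing.assert_array_equal(out, expected)


class TestExtractCohorts:
    def test_single_square(self):
        mask = np.zeros((40, 40), bool)
        mask[10:30, 10:30] = True
        regions = extract_cohorts(mask)
        assert len(regions) == 1
        assert regions[0].area == 400
        assert regions[0].bbox == (10, 10, 30, 30)
        c = regions[0].contour
        np.testing.assert_allclose(c[0], c[-1])  # closed

    def test_two_discs(self):
        mask = np.zeros((64, 64), bool)
        for center in ((16, 16), (48, 48)):
            rr, cc = draw_disk(center, 8)
            mask[rr, cc] = True
        regions = extract_cohorts(mask)
        assert len(regions) == 2
        for r in regions:
            assert r.area == pytest.approx(np.pi * 64, rel=0.1)

    def test_border_touching_contour_closed(self):
        mask = np.zeros((20, 20), bool)
        mask[0:8, 0:8] = True
        regions = extract_cohorts(mask)
        assert len(regions) == 1
        c = regions[0].contour
        np.testing.assert_allclose(c[0], c[-1])
        assert c[:, 0].min() >= 0 and c[:, 1].min() >= 0


class TestAreaAndGrowth:
    def test_empty_masks_zero_series(self):
        ms = MaskSequence([np.zeros((8, 8), bool)] * 3)
        np.testing.assert_array_equal(fibroblast_area_series(ms), [0, 0, 0])

    def test_constant_mask_constant_series(self):
        m = np.zeros((8, 8), bool)
        m[2:5, 2:5] = True
        ms = MaskSequence([m] * 4)
        np.testing.assert_array_equal(fibroblast_area_series(ms), [9] * 4)

    def test_growth_rate_arithmetic(self):
        np.testing.assert_allclose(growth_rate_series([100, 150, 200]),
                                   [1.0, 1.5, 2.0])
        np.testing.assert_allclose(growth_rate_series([7, 7, 7]), [1, 1, 1])

    def test_zero_initial_area_rejected(self):
        with pytest.raises(ValueError):
            growth_rate_series([0, 10])

    def test_phantom_area_series_accuracy(self, segmented_growth_phantom):
        seq, truth, masks = segmented_growth_phantom
        areas = fibroblast_area_series(masks)
        np.testing.assert_allclose(areas, truth.areas, rtol=0.05)
        r = np.corrcoef(areas, truth.areas)[0, 1]
        assert r > 0.99

    def test_phantom_growth_rate_tracks_closed_form(self,
                                                    segmented_growth_phantom):
        seq, truth, masks = segmented_growth_phantom
        g = growth_rate_series(fibroblast_area_series(masks))
        expected = 1.1 ** np.arange(len(g))
        np.testing.assert_allclose(g, expected, rtol=0.05)
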