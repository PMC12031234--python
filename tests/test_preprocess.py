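import numpy as np
import pytest

from lsrm.image_io import ImageSlice
from lsrm.preprocess import (
    PostprocessConfig,
    PreprocessConfig,
    adaptive_hist_eq,
    apply_postprocess,
    apply_preprocess,
    bandpass_filter,
    circular_roi_mask,
    make_noise_pairs,
    median_filter,
    morph_refine,
    subtract_background,
)


def img(arr):
    return ImageSlice.from_array(np.asarray(arr, dtype=np.float64))


class TestSubtractBackground:
    def test_identical_gives_zero(self, random_slice):
        out = subtract_background(random_slice, random_slice)
        np.testing.assert_array_equal(out.pixels, 0.0)

    def test_zero_reference_identity(self, random_slice):
        zero = img(np.zeros(random_slice.shape))
        out = subtract_background(random_slice, zero)
        np.testing.assert_array_equal(out.pixels, random_slice.pixels)

    def test_negative_difference_clipped(self):
        out = subtract_background(img(np.full((4, 4), 0.3)), img(np.full((4, 4), 0.5)))
        np.testing.assert_array_equal(out.pixels, 0.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            subtract_background(img(np.zeros((4, 4))), img(np.zeros((5, 5))))


def brute_force_median(data, k):
    # edge convention: reflect-including-edge (numpy calls this "symmetric")
    h, w = data.shape
    p = k // 2
    padded = np.pad(data, p, mode="symmetric")
    out = np.empty_like(data)
    for i in range(h):
        for j in range(w):
            out[i, j] = np.median(sorted(padded[i : i + k, j : j + k].ravel()))
    return out


class TestMedianFilter:
    def test_constant_unchanged(self):
        out = median_filter(img(np.full((6, 6), 0.4)), 3)
        np.testing.assert_array_equal(out.pixels, 0.4)

    def test_single_impulse_removed(self):
        data = np.zeros((7, 7))
        data[3, 3] = 1.0
        out = median_filter(img(data), 3)
        np.testing.assert_array_equal(out.pixels, 0.0)

    def test_even_kernel_rejected(self, random_slice):
        with pytest.raises(ValueError):
            median_filter(random_slice, 4)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        data = np.random.default_rng(seed).uniform(0, 1, (5, 5))
        out = median_filter(img(data), 3)
        np.testing.assert_allclose(out.pixels, brute_force_median(data, 3))

    def test_brute_force_on_7x7(self, rng):
        data = rng.uniform(0, 1, (7, 7))
        np.testing.assert_allclose(
            median_filter(img(data), 3).pixels, brute_force_median(data, 3)
        )


class TestCircularRoiMask:
    def test_radius_one_on_odd_grid_counts_five(self):
        mask = circular_roi_mask((9, 9), radius=1)
        assert mask.sum() == 5  # center + 4-neighbors

    def test_center_pixel_always_inside(self):
        for shape in [(8, 8), (9, 9), (16, 32)]:
            mask = circular_roi_mask(shape)
            assert mask[(shape[0] - 1) // 2, (shape[1] - 1) // 2]

    def test_large_radius_all_true(self):
        mask = circular_roi_mask((10, 10), radius=100)
        assert mask.all()

    def test_default_radius(self):
        mask = circular_roi_mask((100, 100))
        brute = np.zeros((100, 100), dtype=bool)
        yy, xx = np.mgrid[0:100, 0:100]
        brute[(yy - 49.5) ** 2 + (xx - 49.5) ** 2 <= 45.0**2] = True
        np.testing.assert_array_equal(mask, brute)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            circular_roi_mask((8, 8), radius=0)


class TestAdaptiveHistEq:
    def test_constant_stays_constant(self):
        out = adaptive_hist_eq(img(np.full((32, 32), 0.5)))
        assert out.pixels.var() == 0.0

    def test_output_in_unit_range(self, random_slice):
        out = adaptive_hist_eq(random_slice)
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0

    def test_low_contrast_ramp_range_expands(self):
        ramp = np.tile(np.linspace(0.4, 0.6, 32), (32, 1))
        out = adaptive_hist_eq(img(ramp))
        assert np.ptp(out.pixels) > np.ptp(ramp)

    def test_pixels_outside_mask_unchanged(self, random_slice):
        mask = circular_roi_mask(random_slice.shape, radius=8)
        out = adaptive_hist_eq(random_slice, mask=mask)
        np.testing.assert_array_equal(out.pixels[~mask], random_slice.pixels[~mask])

    def test_nonpositive_clip_limit_rejected(self, random_slice):
        with pytest.raises(ValueError):
            adaptive_hist_eq(random_slice, clip_limit=0.0)


def brute_force_morph(data, reducer):
    # disk(1) = plus-shaped neighborhood, edge values taken from in-frame pixels
    h, w = data.shape
    out = np.empty_like(data)
    for i in range(h):
        for j in range(w):
            vals = [data[i, j]]
            if i > 0:
                vals.append(data[i - 1, j])
            if i < h - 1:
                vals.append(data[i + 1, j])
            if j > 0:
                vals.append(data[i, j - 1])
            if j < w - 1:
                vals.append(data[i, j + 1])
            out[i, j] = reducer(vals)
    return out


class TestMorphology:
    def test_constant_round_trip(self):
        c = img(np.full((8, 8), 0.3))
        out = morph_refine(morph_refine(c, "dilate", 1), "erode", 1)
        np.testing.assert_array_equal(out.pixels, 0.3)

    def test_dilated_impulse_is_plus_shaped(self):
        data = np.zeros((7, 7))
        data[3, 3] = 1.0
        out = morph_refine(img(data), "dilate", 1)
        assert out.pixels.sum() == 5.0
        assert out.pixels[3, 3] == out.pixels[2, 3] == out.pixels[3, 2] == 1.0

    def test_order_property(self, random_slice):
        eroded = morph_refine(random_slice, "erode", 1).pixels
        dilated = morph_refine(random_slice, "dilate", 1).pixels
        assert (eroded <= random_slice.pixels).all()
        assert (random_slice.pixels <= dilated).all()

    def test_matches_brute_force_oracle(self, rng):
        data = rng.uniform(0, 1, (7, 7))
        np.testing.assert_allclose(
            morph_refine(img(data), "dilate", 1).pixels, brute_force_morph(data, max)
        )
        np.testing.assert_allclose(
            morph_refine(img(data), "erode", 1).pixels, brute_force_morph(data, min)
        )

    def test_open_close_compositions(self, random_slice):
        opened = morph_refine(random_slice, "open", 1).pixels
        manual = morph_refine(morph_refine(random_slice, "erode", 1), "dilate", 1).pixels
        np.testing.assert_array_equal(opened, manual)

    def test_invalid_inputs(self, random_slice):
        with pytest.raises(ValueError):
            morph_refine(random_slice, "blur", 1)
        with pytest.raises(ValueError):
            morph_refine(random_slice, "dilate", 0)


class TestBandpassFilter:
    def test_dc_rejection_on_constant(self):
        out = bandpass_filter(img(np.full((16, 16), 0.7)), 1.0, 8.0)
        np.testing.assert_allclose(out.pixels, 0.0, atol=1e-12)

    def test_pass_all_band_is_identity(self, random_slice):
        n = random_slice.shape[0]
        out = bandpass_filter(random_slice, 0.0, float(n))
        np.testing.assert_allclose(out.pixels, random_slice.pixels, atol=1e-10)

    def test_in_band_sinusoid_preserved(self):
        n = 64
        x = np.arange(n)
        tone = 0.5 + 0.3 * np.sin(2 * np.pi * 8 * x / n)
        data = np.tile(tone, (n, 1))
        out = bandpass_filter(img(data), 4.0, 16.0)
        expect = data - 0.5  # DC removed, tone kept
        np.testing.assert_allclose(out.pixels, np.clip(expect, 0, 1), atol=1e-10)

    def test_out_of_band_sinusoid_removed(self):
        n = 64
        x = np.arange(n)
        data = np.tile(0.5 + 0.3 * np.sin(2 * np.pi * 20 * x / n), (n, 1))
        out = bandpass_filter(img(data), 0.0, 10.0)
        np.testing.assert_allclose(out.pixels, 0.5, atol=1e-10)

    def test_cutoffs_out_of_order_rejected(self, random_slice):
        with pytest.raises(ValueError):
            bandpass_filter(random_slice, 5.0, 5.0)
        with pytest.raises(ValueError):
            bandpass_filter(random_slice, -1.0, 5.0)


class TestNoisePairs:
    def test_zero_sigma_identity(self, random_slice):
        plus, minus = make_noise_pairs(random_slice, 0.0, seed=1)
        np.testing.assert_array_equal(plus.pixels, random_slice.pixels)
        np.testing.assert_array_equal(minus.pixels, random_slice.pixels)

    def test_pair_cancellation_without_clipping(self):
        base = img(np.full((64, 64), 0.5))
        plus, minus = make_noise_pairs(base, 0.01, seed=2)
        # sigma small enough that no draw hits the clip boundary
        assert plus.pixels.max() < 1.0 and minus.pixels.min() > 0.0
        np.testing.assert_allclose((plus.pixels + minus.pixels) / 2, 0.5, atol=1e-12)

    def test_sample_std_matches_sigma(self):
        base = img(np.full((128, 128), 0.5))
        plus, _ = make_noise_pairs(base, 0.05, seed=3)
        resid = plus.pixels - base.pixels
        assert abs(resid.std() - 0.05) / 0.05 < 0.10

    def test_same_draw_used_for_both(self):
        base = img(np.full((16, 16), 0.5))
        plus, minus = make_noise_pairs(base, 0.02, seed=4)
        np.testing.assert_allclose(plus.pixels - 0.5, 0.5 - minus.pixels, atol=1e-12)


class TestChains:
    @pytest.mark.parametrize(
        "fn,args",
        [
            (median_filter, (3,)),
            (morph_refine, ("open", 1)),
            (adaptive_hist_eq, ()),
            (bandpass_filter, (0.0, 10.0)),
        ],
    )
    def test_shape_and_range_preserved(self, random_slice, fn, args):
        out = fn(random_slice, *args)
        assert out.shape == random_slice.shape
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0

    def test_apply_preprocess_defaults(self, small_phantom):
        out = apply_preprocess(
            small_phantom.noisy[0], PreprocessConfig(), small_phantom.background[0]
        )
        assert out.shape == small_phantom.noisy[0].shape
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0

    def test_apply_postprocess_defaults(self, random_slice):
        out = apply_postprocess(random_slice, PostprocessConfig())
        assert out.shape == random_slice.shape

    def test_all_steps_switchable(self, small_phantom):
        off = PreprocessConfig(
            background_subtraction=False,
            median_kernel=None,
            roi=False,
            clahe=False,
            morphology_op=None,
        )
        out = apply_preprocess(small_phantom.noisy[0], off)
        np.testing.assert_array_equal(out.pixels, small_phantom.noisy[0].pixels)
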