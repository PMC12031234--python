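import dataclasses

import numpy as np
import pytest

from lsrm.dip import (
    DIPConfig,
    EarlyStopRule,
    build_network,
    denoise_stack,
    early_stop_check,
    fit_dip,
)
from lsrm.image_io import ImageSlice, ImageStack
from lsrm.metrics import psnr, rmse, ssim
from lsrm.phantom import PhantomSpec, generate_spheroid_phantom


class TestBuildNetwork:
    def test_untrained_output_strictly_inside_unit_interval(self, fast_dip_config):
        net = build_network(fast_dip_config, (16, 16))
        out = net.predict()
        assert out.shape == (16, 16)
        assert out.min() > 0.0 and out.max() < 1.0

    def test_same_seed_identical_initial_outputs(self, fast_dip_config):
        a = build_network(fast_dip_config, (16, 16)).predict()
        b = build_network(fast_dip_config, (16, 16)).predict()
        np.testing.assert_array_equal(a, b)

    def test_different_seeds_differ(self, fast_dip_config):
        a = build_network(fast_dip_config, (16, 16)).predict()
        b = build_network(fast_dip_config.replace(seed=9), (16, 16)).predict()
        assert not np.array_equal(a, b)

    def test_parameter_count_monotone_in_base_channels(self, fast_dip_config):
        counts = [
            build_network(fast_dip_config.replace(base_channels=c), (16, 16)).count_parameters()
            for c in (4, 8, 16)
        ]
        assert counts[0] < counts[1] < counts[2]

    def test_non_multiple_shapes_padded_and_cropped(self, fast_dip_config):
        net = build_network(fast_dip_config, (13, 19))
        assert net.padded_shape == (16, 20)
        assert net.predict().shape == (13, 19)

    def test_too_small_image_rejected(self, fast_dip_config):
        with pytest.raises(ValueError, match="too small"):
            build_network(fast_dip_config.replace(depth=5), (16, 16))


def brute_force_early_stop(trace, window, min_delta, patience):
    """Independent replay of the plateau rule."""
    trace = list(trace)
    smoothed = [
        float(np.mean(trace[max(0, i - window + 1) : i + 1])) for i in range(len(trace))
    ]
    keep = int(np.argmin(smoothed))
    blocks = [
        float(np.mean(trace[k * window : (k + 1) * window]))
        for k in range(len(trace) // window)
    ]
    strikes = 0
    for prev, cur in zip(blocks, blocks[1:]):
        if prev - cur < min_delta:
            strikes += 1
        else:
            strikes = 0
    # only trailing strikes count
    trailing = 0
    for prev, cur in reversed(list(zip(blocks, blocks[1:]))):
        if prev - cur < min_delta:
            trailing += 1
        else:
            break
    return trailing >= patience, keep


class TestEarlyStop:
    def test_strictly_decreasing_never_stops(self):
        rule = EarlyStopRule(window=10, min_delta=1e-5, patience=3)
        trace = np.linspace(1.0, 0.0, 200)
        stop, keep = early_stop_check(trace, rule)
        assert not stop
        assert keep == 199

    def test_flat_trace_stops_after_patience_blocks(self):
        rule = EarlyStopRule(window=10, min_delta=1e-5, patience=3)
        stop, _ = early_stop_check(np.ones(39), rule)
        assert not stop
        stop, _ = early_stop_check(np.ones(40), rule)
        assert stop

    def test_plateau_then_decrease_matches_oracle(self):
        rule = EarlyStopRule(window=5, min_delta=1e-4, patience=2)
        trace = np.concatenate(
            [np.linspace(1, 0.5, 20), np.full(15, 0.5), np.linspace(0.5, 0.2, 20)]
        )
        for n in range(5, len(trace) + 1):
            expect = brute_force_early_stop(trace[:n], 5, 1e-4, 2)
            assert early_stop_check(trace[:n], rule) == expect

    def test_random_traces_match_oracle(self, rng):
        rule = EarlyStopRule(window=4, min_delta=1e-3, patience=2)
        for _ in range(20):
            trace = rng.uniform(0, 1, rng.integers(4, 60))
            expect = brute_force_early_stop(trace, 4, 1e-3, 2)
            assert early_stop_check(trace, rule) == expect

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            early_stop_check([], EarlyStopRule())


class TestFitDip:
    def test_constant_target_reproduced(self):
        config = DIPConfig(
            depth=2, base_channels=8, skip_channels=4, input_channels=8,
            iterations_max=300, seed=0,
        )
        target = ImageSlice.from_array(np.full((32, 32), 0.5))
        result = fit_dip(target, config)
        assert np.abs(result.denoised.pixels - 0.5).max() < 0.01

    def test_determinism(self, fast_dip_config, random_slice):
        a = fit_dip(random_slice, fast_dip_config)
        b = fit_dip(random_slice, fast_dip_config)
        np.testing.assert_array_equal(a.denoised.pixels, b.denoised.pixels)
        np.testing.assert_array_equal(a.loss_trace, b.loss_trace)
        assert a.stop_iteration == b.stop_iteration

    def test_output_range_and_shape(self, fast_dip_config, random_slice):
        result = fit_dip(random_slice, fast_dip_config)
        assert result.denoised.shape == random_slice.shape
        assert result.denoised.pixels.min() >= 0.0
        assert result.denoised.pixels.max() <= 1.0

    def test_loss_trace_recorded_every_iteration(self, fast_dip_config, random_slice):
        result = fit_dip(random_slice, fast_dip_config)
        assert 0 < len(result.loss_trace) <= fast_dip_config.iterations_max
        assert result.stop_iteration < len(result.loss_trace)

    def test_kept_iteration_is_prefix_minimum_of_smoothed_loss(
        self, fast_dip_config, random_slice
    ):
        result = fit_dip(random_slice, fast_dip_config)
        _, keep = early_stop_check(result.loss_trace, fast_dip_config.early_stop)
        assert result.stop_iteration == keep

    def test_non_finite_target_rejected(self, fast_dip_config):
        bad = ImageSlice(np.full((16, 16), np.nan), 6.5, "float", False)
        with pytest.raises(ValueError, match="non-finite"):
            fit_dip(bad, fast_dip_config)

    def test_unnormalized_target_rejected(self, fast_dip_config):
        bad = ImageSlice(np.full((16, 16), 2.0), 6.5, "float", False)
        with pytest.raises(ValueError, match="normalized"):
            fit_dip(bad, fast_dip_config)

    def test_denoising_gain_on_phantom_slice(self):
        # raw target, sigma 0.05: the prior alone must beat the noisy input
        spec = PhantomSpec(
            grid_size=64, n_slices=1, spheroid_diameter_um=0.6 * 635,
            noise_sigma=0.05, fluor_amplitude=0.0, seed=5,
        )
        vol = generate_spheroid_phantom(spec)
        result = fit_dip(vol.noisy[0], DIPConfig(iterations_max=300, seed=5))
        assert psnr(vol.clean[0], result.denoised) > psnr(vol.clean[0], vol.noisy[0])
        assert ssim(vol.clean[0], result.denoised) > ssim(vol.clean[0], vol.noisy[0])


class TestDenoiseStack:
    def test_single_slice_stack_reduces_to_fit_dip(self, fast_dip_config, random_slice):
        stack = ImageStack([random_slice])
        denoised, results = denoise_stack(stack, fast_dip_config)
        direct = fit_dip(random_slice, fast_dip_config.replace(seed=fast_dip_config.seed))
        np.testing.assert_array_equal(denoised[0].pixels, direct.denoised.pixels)
        assert len(results) == 1

    def test_identical_slices_differ_only_by_seed(self, fast_dip_config, rng):
        from scipy.ndimage import gaussian_filter

        plane = gaussian_filter(rng.uniform(0, 1, (16, 16)), 2)
        plane = 0.2 + 0.6 * (plane - plane.min()) / np.ptp(plane)
        stack = ImageStack([ImageSlice.from_array(plane) for _ in range(3)])
        denoised, _ = denoise_stack(stack, fast_dip_config.replace(iterations_max=80))
        for i in range(3):
            for j in range(i + 1, 3):
                assert rmse(denoised[i], denoised[j]) < 0.05

    def test_per_slice_seeds_are_config_seed_plus_index(self, fast_dip_config, rng):
        plane = rng.uniform(0.2, 0.8, (16, 16))
        stack = ImageStack([ImageSlice.from_array(plane) for _ in range(3)])
        denoised, results = denoise_stack(stack, fast_dip_config)
        for i in range(3):
            assert results[i].config.seed == fast_dip_config.seed + i
            direct = fit_dip(stack[i], fast_dip_config.replace(seed=fast_dip_config.seed + i))
            np.testing.assert_array_equal(denoised[i].pixels, direct.denoised.pixels)

    def test_shape_and_z_step_preserved(self, fast_dip_config, rng):
        stack = ImageStack.from_array(rng.uniform(0, 1, (2, 16, 16)), z_step_um=10.0)
        denoised, _ = denoise_stack(stack, fast_dip_config)
        assert denoised.data.shape == stack.data.shape
        assert denoised.z_step_um == 10.0

    def test_failure_reports_slice_index(self, fast_dip_config):
        good = ImageSlice.from_array(np.full((16, 16), 0.5))
        bad = ImageSlice(np.full((16, 16), np.nan), 6.5, "float", False)
        stack = ImageStack.__new__(ImageStack)  # bypass validation to inject NaN slice
        stack.slices = [good, bad]
        stack.z_step_um = 10.0
        with pytest.raises(RuntimeError, match="slice 1"):
            denoise_stack(stack, fast_dip_config)


class TestConfigValidation:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            DIPConfig(depth=0)
        with pytest.raises(ValueError):
            DIPConfig(iterations_max=0)
        with pytest.raises(ValueError):
            DIPConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            EarlyStopRule(window=0)
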