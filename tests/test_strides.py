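"""Stride segmentation, toe-off detection, normalization and templates."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.optimize import brentq

from gaitharmonics import (
    GaitSimConfig,
    Stride,
    ThighAngleSeries,
    TimeGrid,
    cascade_for_fft,
    compute_spectrum,
    detect_toe_off,
    find_fundamental,
    fit_stride_model,
    group_by_template,
    mean_template,
    normalize_stride,
    pearson_correlation,
    reconstruct,
    segment_strides,
    simulate_strides,
    simulate_trial,
    stride_frequency_from_time,
)
from gaitharmonics.classify import align_library
from gaitharmonics.errors import (
    InputError,
    InsufficientStridesError,
    ToeOffNotFoundError,
)
from gaitharmonics.harmonic import TWO_PI
from gaitharmonics.strides import NormalizedStride


class TestSegmentStrides:
    def test_periodic_trial_yields_interior_strides(self, clean_config):
        trial = simulate_trial(clean_config)  # 10 strides, zero noise/jitter
        strides = segment_strides(trial.angle, gyro=trial.gyro_dps)
        assert len(strides) == 8
        lengths = {s.n_samples for s in strides}
        assert max(lengths) - min(lengths) <= 1
        assert all(s.stride_time_s == pytest.approx(1.0, abs=0.02) for s in strides)
        assert all(s.gyro_dps is not None for s in strides)

    def test_constant_angle_rejected(self):
        series = ThighAngleSeries(times_s=np.arange(500) / 100.0, angle_deg=np.full(500, 3.0))
        with pytest.raises(InsufficientStridesError):
            segment_strides(series)

    def test_two_stride_trial_empty_after_exclusion(self, clean_config):
        trial = simulate_trial(replace(clean_config, n_strides=2))
        assert segment_strides(trial.angle) == []

    def test_stride_invariant_duration_equals_bounds(self, clean_config):
        trial = simulate_trial(clean_config)
        for s in segment_strides(trial.angle):
            assert s.end_s - s.start_s == pytest.approx(s.stride_time_s)

    def test_loading_response_oscillation_does_not_split_strides(self, clean_config):
        # pattern 6 has the strongest secondary (loading-response) peak
        trial = simulate_trial(replace(clean_config, pattern_sequence=(6,)))
        assert len(segment_strides(trial.angle)) == 8


class TestDetectToeOff:
    def test_analytic_sine_crossing(self):
        t = np.arange(100) / 100.0
        assert detect_toe_off(-np.sin(TWO_PI * t), t) == pytest.approx(0.5, abs=1e-9)

    def test_strictly_positive_signal_rejected(self):
        t = np.arange(10) / 10.0
        with pytest.raises(ToeOffNotFoundError):
            detect_toe_off(np.ones(10), t)

    def test_gyro_template_crossing_matches_bisection_root(self, library):
        """Linear-interpolated crossing agrees with the analytic root of the series."""
        m = library.gyro_models[0]
        grid = TimeGrid(0.0, 1.0, 100.0)
        g = reconstruct(m, grid)
        t_cross = detect_toe_off(g, grid.times())

        def series(x):
            return sum(
                a * np.cos(TWO_PI * (n + 1) * x + p)
                for n, (a, p) in enumerate(zip(m.amplitudes, m.phases))
            )

        root = brentq(series, t_cross - 0.02, t_cross + 0.02)
        assert t_cross == pytest.approx(root, abs=5e-4)


class TestStrideFrequency:
    @pytest.mark.parametrize("t, f", [(1.0, 1.0), (1.25, 0.8)])
    def test_reciprocal(self, t, f):
        assert stride_frequency_from_time(t) == f

    def test_non_positive_rejected(self):
        with pytest.raises(InputError):
            stride_frequency_from_time(0.0)

    def test_agrees_with_fft_fundamental_of_cascaded_stride(self):
        cfg = GaitSimConfig(
            n_strides=1, pattern_sequence=(3,), stride_time_mean_s=1.0 / 0.925,
            stride_time_cv=0.0, noise_deg_sd=0.0, extra_harmonic_frac=0.0,
            gyro_noise_dps_sd=0.0, seed=2,
        )
        stride = simulate_strides(cfg)[0]
        f_time = stride_frequency_from_time(stride.stride_time_s)
        cascaded = cascade_for_fft(stride.angle_deg, 4)
        rate = stride.n_samples / stride.stride_time_s
        f_fft, _ = find_fundamental(compute_spectrum(cascaded, rate))
        assert abs(f_fft - f_time) <= rate / cascaded.size  # within one bin


class TestCascade:
    def test_tiling(self):
        np.testing.assert_array_equal(cascade_for_fft([1, 2], 4), [1, 2, 1, 2, 1, 2, 1, 2])

    def test_single_copy_is_identity(self):
        np.testing.assert_array_equal(cascade_for_fft([3.0, 1.0], 1), [3.0, 1.0])

    def test_fundamental_lands_on_bin_four(self, clean_config):
        stride = simulate_strides(replace(clean_config, n_strides=1))[0]
        cascaded = cascade_for_fft(stride.angle_deg, 4)
        rate = stride.n_samples / stride.stride_time_s
        _, bin_idx = find_fundamental(compute_spectrum(cascaded, rate))
        assert bin_idx == 4


class TestNormalizeStride:
    def test_output_shape_and_range(self, clean_config):
        stride = simulate_strides(replace(clean_config, n_strides=1))[0]
        norm = normalize_stride(stride)
        assert len(norm) == 2000
        assert norm.samples.min() == 0.0 and norm.samples.max() == 1.0
        assert norm.originally_deg_range == pytest.approx((-15.0, 25.0))

    def test_presampled_unit_stride_needs_only_amplitude_normalization(self):
        u = np.arange(2000) / 2000.0
        shape = 3.0 + 2.0 * np.sin(TWO_PI * u)
        stride = Stride(angle_deg=shape, start_s=0.0, end_s=1.0, index_in_trial=0, rate_hz=2000.0)
        norm = normalize_stride(stride)
        np.testing.assert_allclose(norm.samples, (shape - shape.min()) / np.ptp(shape), atol=1e-12)

    def test_template_shape_preserved_through_round_trip(self, clean_config, library):
        # sample at 2000 Hz so the 2000-point resampling is interpolation-free
        stride = simulate_strides(
            replace(clean_config, n_strides=1, pattern_sequence=(5,), rate_hz=2000.0)
        )[0]
        norm = normalize_stride(stride)
        template = align_library(library).thigh_models[4]
        ref = reconstruct(template, TimeGrid(0.0, 1.0, 2000.0))
        assert pearson_correlation(norm.samples, ref) > 1 - 1e-9


class TestTemplateGrouping:
    def _templates(self, library):
        lib = align_library(library)
        out = []
        for m in lib.thigh_models:
            y = reconstruct(m, TimeGrid(0.0, 1.0, 2000.0))
            out.append(NormalizedStride(samples=(y - y.min()) / np.ptp(y)))
        return out

    def test_template_groups_with_itself_at_zero_rmse(self, library):
        templates = self._templates(library)
        grouping = group_by_template([templates[2]], templates)
        assert grouping.groups[2] == [0]
        assert grouping.rmse[0, 2] == 0.0

    def test_uniform_offset_beyond_cutoff_is_unassigned(self, library):
        templates = self._templates(library)
        shifted = NormalizedStride(samples=templates[0].samples + 0.05)
        grouping = group_by_template([shifted], [templates[0]])
        assert grouping.unassigned == [0]
        assert grouping.rmse[0, 0] == pytest.approx(0.05)

    def test_zero_cutoff_assigns_only_exact_copies(self, library):
        templates = self._templates(library)
        near = NormalizedStride(samples=templates[0].samples + 1e-6)
        grouping = group_by_template([templates[0], near], templates, rmse_cutoff=0.0)
        assert grouping.groups[0] == []
        assert set(grouping.unassigned) == {0, 1}

    def test_noisy_strides_group_to_generating_template(self, library):
        templates = self._templates(library)
        rng = np.random.default_rng(4)
        strides, truth = [], []
        for k in range(6):
            for _ in range(10):
                noisy = templates[k].samples + rng.normal(0, 0.01, 2000)
                strides.append(NormalizedStride(samples=(noisy - noisy.min()) / np.ptp(noisy)))
                truth.append(k)
        grouping = group_by_template(strides, templates)
        correct = sum(1 for k, g in grouping.groups.items() for i in g if truth[i] == k)
        assert correct >= 0.95 * len(strides)


class TestMeanTemplate:
    def test_single_stride_is_identity(self, library):
        templates = TestTemplateGrouping()._templates(library)
        mean = mean_template([templates[1]])
        np.testing.assert_allclose(mean.samples, templates[1].samples, atol=1e-12)

    def test_two_mirror_offset_strides_average_to_midpoint_shape(self):
        base = (1 - np.cos(TWO_PI * np.arange(2000) / 2000.0)) / 2
        up = NormalizedStride(samples=np.clip(base + 0.1 * base * (1 - base), 0, None))
        down = NormalizedStride(samples=np.clip(base - 0.1 * base * (1 - base), 0, None))
        mid = mean_template([up, down])
        ref = (base - base.min()) / np.ptp(base)
        np.testing.assert_allclose(mid.samples, ref, atol=1e-9)

    def test_averaging_many_noisy_strides_recovers_template(self, library):
        templates = TestTemplateGrouping()._templates(library)
        rng = np.random.default_rng(9)
        noisy = [
            NormalizedStride(samples=templates[2].samples + rng.normal(0, 0.02, 2000))
            for _ in range(50)
        ]
        mean = mean_template(noisy)
        assert pearson_correlation(mean.samples, templates[2].samples) > 0.999

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            mean_template([])


class TestFitStrideModel:
    def test_noiseless_stride_round_trips_to_generating_model(self, clean_config, library):
        stride = simulate_strides(replace(clean_config, n_strides=1, pattern_sequence=(4,)))[0]
        fitted = fit_stride_model(stride, n_harmonics=5)
        template = align_library(library).thigh_models[3]
        grid = TimeGrid(0.0, stride.stride_time_s, stride.n_samples / stride.stride_time_s)
        np.testing.assert_allclose(reconstruct(fitted, grid), stride.angle_deg, atol=1e-6)
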