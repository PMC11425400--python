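"""Temporal pipeline: matrix transforms, wavelet residual, events,
velocity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import find_peaks

from lymphoscope import (
    BolusEvent,
    CircleROI,
    ImageStack,
    PixelMask,
    PolygonROI,
    TimeSeriesMatrix,
    WaveletParams,
    detect_bolus_peaks,
    matrix_to_stack,
    roi_time_series,
    stack_to_matrix,
    transport_velocity,
    wavelet_residual_transform,
    xcorr_velocity,
    z_normalize_rows,
    znormalize_stack,
)
from lymphoscope.dynamics import _denoise_and_baseline, intensity_mask

from conftest import bolus_scene_snr, detection_roi


def random_stack(rng, shape=(6, 7, 9)):
    return ImageStack(data=rng.random(shape) * 100, pixel_pitch=0.1, frame_interval=0.1)


class TestMatrixTransforms:
    def test_single_pixel_mask_extracts_its_series(self):
        rng = np.random.default_rng(0)
        stack = random_stack(rng, (2, 2, 3))
        mask = np.zeros((2, 2), dtype=bool)
        mask[1, 0] = True
        m = stack_to_matrix(stack, PixelMask(mask))
        assert m.values.shape == (1, 3)
        np.testing.assert_array_equal(m.values[0], stack.data[1, 0, :])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_round_trip_is_identity_on_mask(self, seed):
        """stack -> matrix -> stack reproduces every masked pixel exactly."""
        rng = np.random.default_rng(seed)
        stack = random_stack(rng)
        mask = PixelMask(rng.random((6, 7)) > 0.4)
        if mask.n_pixels == 0:
            return
        m = stack_to_matrix(stack, mask)
        back = matrix_to_stack(m, mask, stack.frame_shape)
        np.testing.assert_array_equal(back.data[mask.mask, :], stack.data[mask.mask, :])
        assert np.all(back.data[~mask.mask, :] == 0)

    def test_rows_match_source_pixels_elementwise(self):
        rng = np.random.default_rng(3)
        stack = random_stack(rng, (4, 4, 5))
        mask = PixelMask(np.ones((4, 4), dtype=bool))
        m = stack_to_matrix(stack, mask)
        assert m.values.shape == (16, 5)
        for r, flat in enumerate(mask.indices):
            i, j = np.unravel_index(flat, (4, 4))
            np.testing.assert_array_equal(m.values[r], stack.data[i, j, :])

    def test_empty_mask_rejected(self):
        stack = random_stack(np.random.default_rng(0))
        with pytest.raises(ValueError):
            stack_to_matrix(stack, PixelMask(np.zeros((6, 7), dtype=bool)))

    def test_row_count_mismatch_rejected(self):
        m = TimeSeriesMatrix(values=np.zeros((3, 4)), frame_interval=0.1)
        with pytest.raises(ValueError):
            matrix_to_stack(m, PixelMask(np.ones((2, 2), dtype=bool)), (2, 2))


class TestZNormalization:
    def test_two_point_row_fixes_population_sd_convention(self):
        m = TimeSeriesMatrix(values=np.array([[0.0, 1.0]]), frame_interval=1.0)
        np.testing.assert_allclose(z_normalize_rows(m).values, [[-1.0, 1.0]])

    def test_constant_row_zeroed_and_flagged(self):
        m = TimeSeriesMatrix(values=np.array([[5.0, 5.0, 5.0], [0.0, 1.0, 2.0]]),
                             frame_interval=1.0)
        z = z_normalize_rows(m)
        assert np.all(z.values[0] == 0.0)
        assert list(z.degenerate_rows) == [0]

    def test_gaussian_rows_standardised_to_machine_precision(self):
        rng = np.random.default_rng(8)
        m = TimeSeriesMatrix(values=rng.normal(50, 7, (20, 256)), frame_interval=0.1)
        z = z_normalize_rows(m)
        assert np.abs(z.values.mean(axis=1)).max() < 1e-12
        assert np.abs(z.values.std(axis=1, ddof=0) - 1).max() < 1e-12

    def test_wrong_provenance_rejected(self):
        m = TimeSeriesMatrix(values=np.zeros((1, 8)), frame_interval=0.1,
                             provenance="z_normalized")
        with pytest.raises(ValueError):
            z_normalize_rows(m)


class TestWaveletResidual:
    def _z(self, values):
        return TimeSeriesMatrix(values=np.atleast_2d(values), frame_interval=0.1,
                                provenance="z_normalized")

    def test_zero_row_maps_to_zero(self):
        out = wavelet_residual_transform(self._z(np.zeros(64)))
        assert np.all(out.values == 0.0)

    def test_slow_trend_absorbed_by_baseline(self):
        # one sinusoid cycle over 8192 samples: period 32x the level-8
        # scale, so the approximation captures it almost entirely
        n = 8192
        y = np.sin(2 * np.pi * np.arange(n) / n)
        y = (y - y.mean()) / y.std()
        out = wavelet_residual_transform(self._z(y))
        assert out.values.max() < 1e-3

    def test_sharp_bumps_survive_as_residual_maxima(self):
        rng = np.random.default_rng(7)
        n = 512
        t = np.arange(n)
        bump_frames = [60, 160, 260, 360, 460]
        y = 2 * np.sin(2 * np.pi * t / n) + rng.normal(0, 0.5, n)
        for b in bump_frames:
            y[b - 1 : b + 2] += [2.5, 5.0, 2.5]
        y = (y - y.mean()) / y.std()
        out = wavelet_residual_transform(self._z(y))
        r = out.values[0]
        idx, _ = find_peaks(r, prominence=0.25 * (r.max() - r.min()))
        assert len(idx) == len(bump_frames)
        assert np.abs(np.asarray(bump_frames) - idx).max() <= 1

    def test_output_nonnegative_for_random_rows(self):
        rng = np.random.default_rng(1)
        out = wavelet_residual_transform(self._z(rng.normal(0, 1, (10, 300))))
        assert np.all(out.values >= 0.0)
        assert out.provenance == "residual_squared"

    def test_level_capped_for_short_series(self):
        p = WaveletParams()
        assert p.capped_level(4096) == 8
        assert p.capped_level(300) == 7
        assert p.capped_level(60) == 4
        assert p.capped_level(8) == 2

    def test_series_shorter_than_four_rejected(self):
        with pytest.raises(ValueError):
            wavelet_residual_transform(self._z(np.zeros(3)))

    @pytest.mark.parametrize("snr", [2.0, 5.0, 20.0])
    def test_denoising_reduces_mse_to_clean_signal(self, snr):
        rng = np.random.default_rng(21)
        n = 512
        clean = np.sin(2 * np.pi * np.arange(n) / 128)
        noise_sd = np.sqrt((clean**2).mean()) / snr
        noisy = clean + rng.normal(0, noise_sd, n)
        denoised, _, _ = _denoise_and_baseline(noisy, WaveletParams())
        assert ((denoised - clean) ** 2).mean() < ((noisy - clean) ** 2).mean()


class TestRoiSeries:
    def test_single_pixel_roi(self):
        rng = np.random.default_rng(2)
        stack = random_stack(rng, (8, 8, 6))
        mask = np.zeros((8, 8), dtype=bool)
        mask[3, 4] = True
        np.testing.assert_array_equal(roi_time_series(stack, mask), stack.data[3, 4, :])

    def test_uniform_frames_give_constant_series(self):
        stack = ImageStack(data=np.full((5, 5, 4), 9.0), pixel_pitch=0.1, frame_interval=0.1)
        np.testing.assert_array_equal(
            roi_time_series(stack, CircleROI(cx=2, cy=2, radius=1.5)), np.full(4, 9.0)
        )

    def test_circle_matches_pixel_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        stack = random_stack(rng, (20, 20, 7))
        roi = CircleROI(cx=9.0, cy=11.0, radius=4.2)
        member = [
            (r, c)
            for r in range(20)
            for c in range(20)
            if (c - 9.0) ** 2 + (r - 11.0) ** 2 <= 4.2**2
        ]
        oracle = np.mean([stack.data[r, c, :] for r, c in member], axis=0)
        np.testing.assert_allclose(roi_time_series(stack, roi), oracle)

    def test_polygon_roi_mask(self):
        roi = PolygonROI(vertices=[[1, 1], [6, 1], [6, 6], [1, 6]])
        mask = roi.to_mask((8, 8))
        assert mask[3, 3] and not mask[0, 0]

    def test_empty_intersection_rejected(self):
        stack = ImageStack(data=np.zeros((5, 5, 2)), pixel_pitch=0.1, frame_interval=0.1)
        with pytest.raises(ValueError):
            roi_time_series(stack, np.zeros((5, 5), dtype=bool))


class TestDetectBolusPeaks:
    def test_constant_series_gives_no_events(self):
        assert detect_bolus_peaks(np.full(50, 3.0), 0.1) == []

    def test_single_triangular_pulse(self):
        y = np.zeros(50)
        y[20:25] = [1, 2, 4, 2, 1]
        events = detect_bolus_peaks(y, 0.1, smooth_s=0.0)
        assert len(events) == 1
        assert events[0].frame_index == 22
        assert events[0].time == pytest.approx(2.2)

    def test_boundary_events_flagged(self):
        y = np.zeros(60)
        y[2] = 5.0
        y[30] = 5.0
        events = detect_bolus_peaks(y, 0.1, smooth_s=0.0, min_separation_s=0.1)
        flags = {e.frame_index: e.near_boundary for e in events}
        assert flags[2] and not flags[30]

    def test_five_boluses_recovered_within_one_frame(self, scattering, small_swir_camera):
        """Full pipeline on a simulated 5-bolus train at SNR 10: five
        events, each within one frame of the true transit time."""
        stack, truth = bolus_scene_snr(
            10.0, 7.0, (5.0, 6.5, 8.0, 9.5, 11.0), 30.0, seed=2,
            camera=small_swir_camera, model=scattering,
        )
        roi = detection_roi(100)
        proc = znormalize_stack(stack, intensity_mask(stack, roi))
        events = detect_bolus_peaks(roi_time_series(proc, roi), stack.frame_interval)
        true_times = truth.arrival_times(0, 9.0)
        assert len(events) == 5
        for e, t in zip(events, true_times):
            assert abs(e.time - t) <= stack.frame_interval + 1e-9


class TestTransportVelocity:
    def _ev(self, t, roi="1"):
        return BolusEvent(time=t, frame_index=int(round(t * 10)), roi_id=roi)

    def test_single_pair_distance_over_time(self):
        est = transport_velocity([self._ev(2.0)], [self._ev(3.0, "2")], 5.0)
        assert est.velocity == pytest.approx(5.0)
        assert est.transit_time == pytest.approx(1.0)

    def test_simultaneous_events_rejected(self):
        est = transport_velocity([self._ev(2.0)], [self._ev(2.0, "2")], 5.0)
        assert est.empty
        assert np.isnan(est.velocity)

    def test_downstream_event_after_next_upstream_not_matched(self):
        # the 4.5 s downstream event falls after the second upstream
        # event, so it can only pair with that one
        est = transport_velocity(
            [self._ev(1.0), self._ev(4.0)], [self._ev(4.5, "2")], 7.0
        )
        assert len(est.matched_pairs) == 1
        assert est.matched_pairs[0][0].time == 4.0
        assert len(est.unmatched_1) == 1

    def test_velocity_recovered_from_simulation(self, scattering, small_swir_camera):
        """True 7 mm/s transport recovered within 10% (0.1 s frame
        quantization on a 2 s transit)."""
        stack, _ = bolus_scene_snr(
            10.0, 7.0, (20.0,), 52.0, seed=4, camera=small_swir_camera, model=scattering
        )
        events = []
        for cx in (20, 160):  # 14 mm apart along the vessel
            roi = detection_roi(cx)
            proc = znormalize_stack(stack, intensity_mask(stack, roi))
            events.append(
                detect_bolus_peaks(roi_time_series(proc, roi), stack.frame_interval)
            )
        est = transport_velocity(events[0], events[1], 14.0)
        assert est.velocity == pytest.approx(7.0, rel=0.10)

    def test_xcorr_estimator_agrees_on_clean_series(self):
        t = np.arange(300) * 0.1
        pulse = np.exp(-((t - 10.0) ** 2) / 0.5)
        shifted = np.exp(-((t - 12.0) ** 2) / 0.5)
        v = xcorr_velocity(pulse, shifted, 0.1, path_distance=14.0)
        assert v == pytest.approx(7.0, rel=0.05)

    def test_nonpositive_path_rejected(self):
        with pytest.raises(ValueError):
            transport_velocity([self._ev(1.0)], [self._ev(2.0)], 0.0)


def test_intensity_mask_selects_bright_pixels():
    data = np.zeros((10, 10, 3))
    data[4:6, :, :] = 100.0
    stack = ImageStack(data=data, pixel_pitch=0.1, frame_interval=0.1)
    mask = intensity_mask(stack, quantile=0.9)
    assert mask.mask[4:6, :].all()
    assert not mask.mask[0, 0]
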