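"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from lymphoscope import (
    BolusTrain,
    CameraModel,
    CircleROI,
    Polyline,
    ScatteringModel,
    VesselSpec,
    extract_profile,
    find_profile_peaks,
    peak_intensity_for_snr,
    scattering_sigma,
    simulate_lymph_stack,
    vessel_distinguishability,
)
from lymphoscope.synthetic import blur_attenuation


@pytest.fixture
def scattering():
    return ScatteringModel()


@pytest.fixture
def small_swir_camera():
    return CameraModel(rows=28, cols=200, band="SWIR")


def brute_force_prominences(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exhaustive prominence oracle, independent of scipy.

    A peak is a strict local maximum (plateaus excluded — random float
    profiles have none).  Its prominence is its height minus the higher
    of the two base levels, where each base is the minimum of the
    samples between the peak and the nearest strictly higher sample on
    that side (or the profile end when none is higher).
    """
    y = np.asarray(y, dtype=float)
    peaks = [i for i in range(1, len(y) - 1) if y[i] > y[i - 1] and y[i] > y[i + 1]]
    proms = []
    for i in peaks:
        left = y[:i][::-1]
        higher = np.nonzero(left > y[i])[0]
        lbase = left[: higher[0] + 1].min() if higher.size else left.min()
        right = y[i + 1 :]
        higher = np.nonzero(right > y[i])[0]
        rbase = right[: higher[0] + 1].min() if higher.size else right.min()
        proms.append(y[i] - max(lbase, rbase))
    return np.array(peaks, dtype=int), np.array(proms)


def make_two_vessel_scene(band: str, blur_rate: float | None = None, seed: int = 5):
    """Static two-vessel frame plus the analysis line crossing both.

    Two parallel 0.22 mm vessels 1 mm apart at 2 mm depth; returns the
    background-subtracted noiseless frame and the perpendicular line.
    """
    model = ScatteringModel()
    if blur_rate is not None:
        model.blur_rate = dict(model.blur_rate, **{band: blur_rate})
    cam = CameraModel(rows=60, cols=80, band=band)
    vessels = [
        VesselSpec(centerline=[[1.0, 2.4], [6.9, 2.4]], true_width=0.22, depth=2.0, peak_intensity=3000),
        VesselSpec(centerline=[[1.0, 3.4], [6.9, 3.4]], true_width=0.22, depth=2.0, peak_intensity=2400),
    ]
    stack, _ = simulate_lymph_stack(
        vessels, [None, None], model, cam, duration=0.1, seed=seed,
        add_noise=False, baseline_fraction=1.0,
    )
    frame = stack.frame(0) - model.background_level[band]
    line = Polyline(vertices=[[40, 4], [40, 54]], calibration=0.1)
    return frame, line


def two_vessel_metrics(band: str, blur_rate: float | None = None):
    frame, line = make_two_vessel_scene(band, blur_rate)
    prof = extract_profile(frame, line)
    peaks = find_profile_peaks(prof)
    metrics = vessel_distinguishability(peaks, line.arclength_mm / 10.0)
    metrics.band = band
    return metrics


def bolus_scene_snr(snr: float, velocity: float, start_times, duration: float,
                    seed: int, camera: CameraModel, model: ScatteringModel):
    """Single-vessel bolus simulation at a target measured SNR."""
    att = blur_attenuation(0.22, scattering_sigma(model, camera.band, 2.0))
    peak = peak_intensity_for_snr(snr, camera, model.background_level[camera.band], attenuation=att)
    vessel = VesselSpec(
        centerline=[[1.0, 1.4], [19.0, 1.4]], true_width=0.22, depth=2.0, peak_intensity=peak
    )
    train = BolusTrain(velocity=velocity, start_times=tuple(start_times), bolus_length=2.0)
    return simulate_lymph_stack([vessel], [train], model, camera, duration=duration, seed=seed)


def detection_roi(cx: float) -> CircleROI:
    return CircleROI(cx=cx, cy=14, radius=3, roi_id=f"x{cx}")
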