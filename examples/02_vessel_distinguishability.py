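"""Vessel distinguishability and resolution of a two-vessel scene.

Renders the same pair of 0.22 mm lymphatic vessels (1 mm apart, 2 mm
deep) through the default NIR-I and SWIR scattering models, draws one
line across both, and computes the two architectural statistics:

* distinguishability = sum(peak prominences) / (vessels per cm of line)
* resolution = FWHM of each vessel peak, mm

The SWIR/NIR ratios summarise the dual-band advantage: > 1 for
distinguishability (cleaner peaks), < 1 for resolution (narrower
peaks).
"""

from lymphoscope import (
    CameraModel,
    Polyline,
    ScatteringModel,
    VesselSpec,
    compare_channels,
    extract_profile,
    find_profile_peaks,
    simulate_lymph_stack,
    vessel_distinguishability,
)

model = ScatteringModel()
vessels = [
    VesselSpec(centerline=[[1.0, 2.4], [6.9, 2.4]], true_width=0.22, depth=2.0, peak_intensity=3000),
    VesselSpec(centerline=[[1.0, 3.4], [6.9, 3.4]], true_width=0.22, depth=2.0, peak_intensity=2400),
]
line = Polyline(vertices=[[40, 4], [40, 54]], calibration=0.1)

metrics = {}
for band in ("NIR", "SWIR"):
    camera = CameraModel(rows=60, cols=80, band=band)
    stack, _ = simulate_lymph_stack(
        vessels, [None, None], model, camera, duration=0.1, seed=5,
        add_noise=False, baseline_fraction=1.0,
    )
    frame = stack.frame(0) - model.background_level[band]
    peaks = find_profile_peaks(extract_profile(frame, line))
    m = vessel_distinguishability(peaks, line.arclength_mm / 10.0)
    m.band = band
    metrics[band] = m
    print(f"{band:>4}: {m.n_vessels} vessels, distinguishability {m.distinguishability:.3f}, "
          f"resolution {m.resolution_mean:.2f} +/- {m.resolution_sd:.2f} mm")

ratios = compare_channels(metrics["SWIR"], metrics["NIR"])
print(f"SWIR/NIR distinguishability ratio: {ratios['distinguishability_ratio']:.2f} (> 1: SWIR cleaner)")
print(f"SWIR/NIR resolution ratio:         {ratios['resolution_ratio_mean']:.2f} (< 1: SWIR sharper)")
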