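"""Dual-band composite: NIR-I in purple, SWIR in green.

Simulates the same scene in both bands (as from co-registered
cameras), composites the frames into one RGB image — NIR drives the
red and blue channels, SWIR the green, so overlap renders white — and
writes a PNG.  The printed pixel values confirm the colour
conventions.
"""

from pathlib import Path

import numpy as np

from lymphoscope import CameraModel, ScatteringModel, VesselSpec, overlay_channels, simulate_lymph_stack
from lymphoscope.io import write_composite_png

model = ScatteringModel()
vessels = [VesselSpec(centerline=[[1.0, 2.4], [6.9, 2.4]], true_width=0.3, depth=2.0, peak_intensity=3000)]
frames = {}
for band in ("NIR", "SWIR"):
    camera = CameraModel(rows=60, cols=80, band=band)
    stack, _ = simulate_lymph_stack(vessels, [None], model, camera, duration=0.1,
                                    seed=3, baseline_fraction=1.0)
    frames[band] = stack.frame(0).astype(float)

composite = overlay_channels(frames["NIR"], frames["SWIR"])
rgb = composite["rgb"]
on_vessel = rgb[24, 40]
background = rgb[5, 40]
print(f"channel mapping: {composite['provenance']}")
print(f"on-vessel RGB  {np.round(on_vessel, 2)}  (bright in both bands -> near white)")
print(f"background RGB {np.round(background, 2)}  (NIR background higher -> purple cast)")

out = Path("scratch") if Path("scratch").is_dir() else Path(".")
png = write_composite_png(composite, out / "overlay.png")
print(f"composite written to {png}")
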