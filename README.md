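# lymphoscope

Quantification of lymphatic vessel architecture and transport from
dynamic NIR-I / SWIR fluorescence image stacks.

The lymphatic system moves lymph as discrete boluses propelled by
intrinsic vessel contraction.  Fluorescence lymphangiography — an
intradermal contrast bolus (indocyanine green in the NIR-I window,
700–900 nm, or SWIR-emitting probes such as Ag₂S quantum dots,
900–1800 nm) imaged at video rate — records both the vessel
architecture and that pumping, but tissue scattering blurs vessels and
slow contrast accumulation buries the transient bolus signal.
lymphoscope is a library for researchers analysing such recordings.
It provides:

* **Cross-section statistics** — from a line drawn across vessels in a
  background-subtracted, max-normalized frame:
  *vessel distinguishability* `D = Σ(peak prominences) / (vessels/cm)`
  and *resolution*, the FWHM (mm) of each vessel peak, plus SWIR/NIR
  ratio tables.
* **A time-series pipeline** for pumping function — mask the stack,
  Z-normalize each pixel's series, wavelet-denoise (symlet-8, level 8,
  empirical-Bayes posterior-median thresholding), subtract the smooth
  approximation-only baseline and square the residual, fold back into
  a stack.  Bolus transits appear as sharp nonnegative peaks; pairing
  transits between two ROIs on a vessel yields the transport velocity
  (mm/s).
* **A synthetic scene simulator** with ground truth — tubular vessels
  of known width, advected bolus trains, depth- and band-dependent
  Gaussian scattering blur, autofluorescence background and
  Poisson–Gaussian 16-bit camera noise — used to validate every
  estimator by recovery.
* **I/O and compositing** — multi-page TIFF stacks with JSON
  calibration sidecars, ROI/polyline JSON, metrics/event/velocity CSV,
  and dual-band RGB composites (NIR purple, SWIR green, overlap
  white).

## Worked example

`examples/03_bolus_velocity.py` simulates a vessel carrying three
boluses at a known 7 mm/s, runs the pipeline, and recovers the
velocity from two ROIs 14 mm apart:

```
simulated 450 frames at 10 fps, true velocity 7.0 mm/s
  roi@2mm: boluses at 10.1 s, 20.2 s, 30.1 s
  roi@16mm: boluses at 12.2 s, 22.2 s, 32.2 s
recovered velocity: 6.78 +/- 0.19 mm/s over 3 bolus pairs (mean transit 2.1 s over 14 mm)
```

Each bolus is detected at both ROIs; the ~2.1 s transit over 14 mm
gives 6.8 mm/s, within the ±0.1 s frame-quantization error of the
true 7 mm/s.  The other examples cover the scattering phantom
(`01`, apparent width vs depth per band), architectural statistics
(`02`, SWIR/NIR distinguishability ratio 1.16 and resolution ratio
0.56 on a two-vessel scene), and dual-band compositing (`04`).

A thin CLI wraps the same library calls:

```sh
lymphoscope simulate invivo --config scene.yaml --out run/ --seed 1
lymphoscope profile --image run/stack.tif --line line.json --out metrics.csv
lymphoscope dynamics --stack run/stack.tif --mask rois.json --out processed/
lymphoscope velocity --events1 e1.csv --events2 e2.csv --path vessel.json --out v.csv
lymphoscope overlay --nir nir.tif --swir swir.tif --out composite.png
```

## Layout

```
src/lymphoscope/   stack.py      calibrated ImageStack container
                   synthetic.py  scene simulator + ground truth
                   profiles.py   cross-section statistics
                   dynamics.py   time-series pipeline, events, velocity
                   ebayes.py     posterior-median wavelet shrinkage
                   io.py         TIFF/JSON/CSV/PNG readers and writers
                   cli.py        thin command-line surface
examples/          one narrative script per capability
docs/methods.md    models, parameters, numerical choices, limitations
tests/             pytest suite (unit, property, end-to-end recovery)
```
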