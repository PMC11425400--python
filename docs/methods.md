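# Methods

lymphoscope quantifies lymphatic vessel architecture and pumping
function from dynamic fluorescence image stacks acquired in the first
near-infrared window (NIR-I, 700–900 nm) and the shortwave infrared
(SWIR, 900–1800 nm).  This note records the models, the parameters
that matter, the numerical choices, and what the synthetic data do and
do not establish.

## Architectural statistics

A user-drawn polyline across one or more vessels in a
background-subtracted, max-normalized frame yields a cross-section
profile, sampled by bilinear interpolation at one pixel pitch along
arclength.  Two statistics summarise the architecture:

**Vessel distinguishability.**  With peaks detected by topographic
prominence (a peak's height above the higher of the two lowest points
separating it from higher terrain or the profile edge),

    D = Σ(prominences) / (n_vessels / L_cm)

where `n_vessels` is the detected peak count and `L_cm` the drawn-line
arclength in cm.  The denominator is a density, so the same peaks on a
longer line give a larger `D`; this is implemented exactly as defined,
not "corrected".  `D = 0` when no peak passes the thresholds.

**Resolution.**  The full width at half maximum of each vessel peak,
in mm, found by linear interpolation walking outward from the apex.
The default reference level is half the peak *height* (profiles are
background-subtracted, so the baseline is ≈ 0); a config flag switches
to half-prominence for strongly overlapped peaks.  A width is reported
as NaN when a half-max crossing is blocked by the profile edge or by
terrain higher than the apex — overlapped peaks whose shared saddle
stays above half height have no well-defined individual FWHM.

Peak-finding defaults: `min_prominence = 0.05` of the normalized
maximum, `min_separation = 0.3 mm`.  These are empirical, exposed in
every API and recorded in output metadata; no claim is made that they
match any particular prior analysis.  Peak detection is delegated to
`scipy.signal.find_peaks`, whose prominence definition is the standard
topographic one (verified exactly against exhaustive search in the
test suite).  For plateau maxima scipy reports the plateau midpoint;
continuous image profiles essentially never contain exact plateaus.

Scale invariance: with max-normalization on, both statistics are
invariant to positive rescaling of the raw intensities (exposure,
gain), which is what makes cross-band ratios meaningful.  Channel
comparisons report the distinguishability ratio and per-matched-peak
resolution ratios (mean ± sd); the resolution ratio is undefined
("NA") when the two channels detect different peak counts.

## Time-series pipeline

Lymph moves as discrete boluses driven by intrinsic vessel
contraction; at a fixed region of interest a bolus is a transient
intensity peak over a slowly varying background of accumulating
contrast.  The pipeline isolates those transients in five steps:

1. **Mask** the stack to pixels of interest — a hand-drawn ROI, a
   mask image, or an intensity criterion (`intensity_mask`: pixels at
   or above a quantile of the temporal-mean image, default the median,
   optionally inside an ROI).  Intensity masking matters: off-vessel
   pixels carry no bolus signal, and Z-normalization amplifies their
   noise to unit variance, diluting ROI averages.
2. **Unroll** to a (pixel × time) matrix and **Z-normalize** each row:
   subtract the row mean, divide by the population sd (ddof = 0; the
   convention is pinned by the two-point case {0, 1} → {−1, +1}).
   Constant rows are zeroed and flagged degenerate.
3. **Wavelet-denoise** each row: symlet-8 ("sym8") discrete wavelet
   transform at decomposition level 8, empirical-Bayes posterior-median
   thresholding of every detail band, with a single noise estimate
   shared across levels (MAD of the finest detail band / 0.6745).
4. **Baseline residual**: reconstruct a smooth baseline from only the
   final-level approximation (scaling) coefficients with all detail
   bands zeroed, subtract it from the denoised row, and square the
   difference.  Squaring guarantees nonnegativity; the baseline absorbs
   slow contrast accumulation so only transients survive.
5. **Fold** the matrix back into a stack (unmasked pixels zero); the
   mask round trip is an exact bijection.

"Level 8" and "symlet 8" are distinct knobs that happen to share a
default; both are configurable.  For series shorter than 2^9 samples
the level is capped at `min(8, floor(log2 n) − 1)` and the cap is
recorded in output metadata.  The cap deliberately ignores the usual
filter-length heuristic (`pywt.dwt_max_level`): the baseline must live
at a coarser scale than any bolus transient, so short series keep the
deepest dyadic level available, with symmetric boundary extension
absorbing the filter overhang.  A practical consequence: recordings
should be long relative to the bolus — with only ~100 frames the
capped baseline partially tracks a slow bolus and the squared residual
grows precursor side lobes.

### Empirical-Bayes shrinkage

No installed package provides the posterior-median rule, so it is
implemented from the published closed forms (`lymphoscope.ebayes`):
each standardised coefficient is modelled as zero with probability
1 − w or drawn from a Laplace(a = 0.5) slab; w is fitted per band by
marginal maximum likelihood (bisection on the monotone score, floored
at the weight corresponding to the universal threshold √(2 log n));
the estimate is the posterior median — exactly zero below a
data-driven threshold, mildly shrunk far above it.  Mills-ratio
asymptotics guard the normal cdf/pdf quotients against overflow.
With an estimated noise level of zero (noiseless input) coefficients
pass through unshrunk.

### Event detection and velocity

Bolus transits are peaks of the residual-squared ROI time series
(per-frame mean over the ROI), found by the same prominence rule on
the time axis.  The series is first smoothed with a 0.3 s boxcar: a
transit spans several consecutive frames while residual noise spikes
are single-frame, so the short average favours real transits.
Defaults: `min_prominence` = 0.25 of the smoothed series range,
`min_separation` = 0.5 s; all exposed.  Events within 5 frames of
either end are flagged `near_boundary` (wavelet edge effects).

Transport velocity uses two ROIs on the same vessel: each upstream
event is greedily matched to the earliest downstream event strictly
after it and before the next upstream event; the per-pair velocity is
path arclength / transit time and the estimate is the mean ± sd over
pairs (flagged empty, not an exception, when no valid pair exists).
An independent cross-correlation lag estimator (`xcorr_velocity`) is
provided as a cross-check.  At 10 fps a transit time of Δt s carries
±0.1 s quantization, i.e. a relative velocity error of ±0.1/Δt.

## Synthetic scenes

The simulator generates the structures the analysis assumes, with full
ground truth:

* **Vessels**: tubes of true width 0.22 mm by default — the anatomical
  lymphatic diameter measured post-mortem with Evan's blue dye — along
  arbitrary centreline polylines, rendered with linear antialiasing so
  the cross-section integrates to the true width.
* **Scattering**: isotropic Gaussian PSF whose sigma grows linearly
  with depth at a per-band rate, default 0.12 mm/mm (NIR-I) and
  0.06 mm/mm (SWIR).  The underlying truth here is only qualitative —
  SWIR scatters less — so the rates are configuration, not physics;
  nothing downstream asserts the in vivo inflation magnitude.
* **Boluses**: 1-D Gaussian packets in arclength (FWHM =
  `bolus_length`, default 2 mm) advected at constant velocity, default
  7 mm/s, inside the measured in vivo regime (7.06 ± 1.58 mm/s); a
  resting baseline (25% of peak intensity) persists between boluses.
* **Background and noise**: uniform per-band autofluorescence
  (default 300 counts NIR-I, 100 SWIR; an optional seeded
  low-frequency field emulates heterogeneity), then Poisson shot noise
  and Gaussian read noise (default 10 counts RMS), clipped to the
  16-bit range.  Camera geometry defaults to the dual-camera setup
  (512×512 NIR-I emICCD, 512×640 SWIR InGaAs).
* **Calibration**: 0.1 mm/pixel and 10 fps by default.  The frame rate
  is a stand-in for unspecified "video rate" acquisition; at 10 fps a
  7 mm/s bolus advances 0.7 mm/frame, comfortably resolvable.

**SNR convention.**  Test scenes are parameterised by the measured
bolus SNR: the post-blur bolus amplitude at the vessel-centre pixel
divided by the RMS noise of the resting signal
(√(gain·counts + read²)).  `peak_intensity_for_snr` inverts the noise
model including the transverse PSF attenuation 2Φ(w/2σ) − 1, so "SNR
5" describes the recorded data, not an unobservable pre-blur quantity.

Determinism: one `numpy` Generator seeded per simulation; identical
configuration and seed give bit-identical stacks.

### Scaling of validation scenes

Validation simulations run on camera subarrays (28×200 px for dynamic
scenes, 64×120 px phantoms, 0.1 mm/px) rather than full frames —
sensor area is a free parameter and no asserted property depends on
it.  Velocity-recovery scenes use 52 s recordings (520 frames) so the
full level-8 decomposition is admissible; bolus-count scenes use 30 s.

### What the synthetic data do not show

The generator reproduces the statistical structure of dynamic
lymphangiography, not its physics: no radiative transport or photon
Monte Carlo, no fluorophore photochemistry or clearance kinetics, no
motion, no vessel branching, and a PSF that is Gaussian by fiat.
Passing recovery tests therefore demonstrates that the estimators are
correct for data obeying the stated model, and says nothing about
model mismatch on real tissue — in particular, the ~5× apparent-width
inflation reported in vivo depends on the real tissue PSF, which the
simulator does not claim to know.

## Known limitations

* FWHM of strongly overlapped vessels is reported NaN rather than
  deconvolved; use half-prominence mode for partial credit.
* Greedy event pairing assumes boluses do not overtake one another and
  that the inter-bolus interval exceeds the transit time between the
  two ROIs; violations surface as unmatched events.
* The residual-squared transform loses the sign and scale of the
  original intensities; event `peak_value`s are comparable within one
  series only.
* Composites assume pre-aligned inputs; co-registration is out of
  scope.
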