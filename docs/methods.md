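# Methods

This note documents the models implemented in `oisflow`, the defaults
and their rationale, what the synthetic generator does and does not
emulate, and the numerical choices a user may want to revisit.

## Acquisition model

Four illumination channels (LEDs at 525/590/625 nm and a 780 nm laser)
share one camera in round-robin at 30 Hz total, 7.5 Hz per channel,
14 ms exposure. Channel *i* is phase-shifted by *i*/30 s; analysis
aligns channels by sample index (nearest-sample alignment). The
residual ≤ 0.1 s misalignment is negligible at the 0.3 Hz analysis
bandwidth, but it does break bit-exact algebraic round trips; tests of
exactness therefore use `AcquisitionConfig(simultaneous_channels=True)`,
which models beam-split simultaneous sampling.

The stimulation protocol is 7 blocks of 10 s stimulation + 40 s rest,
each onset delayed by an independent `U(0, 3 s)` jitter (anticipation
control). The whisker deflection rate is stored as metadata only (it
never enters the analysis). The acquisition prepends a 20 s rest
baseline and appends a 10 s tail.

## Ground-truth hemodynamics (synthetic generator)

The evoked response to a sustained stimulus is a regularized
incomplete-gamma rise `P(k, t/τ_rise)` (defaults k = 2, τ_rise = 1.5 s)
saturating toward a plateau during the 10 s stimulation, followed by an
exponential return (τ_decay = 2 s) after offset. The profile is
normalized so its supremum during stimulation is exactly the requested
peak amplitude, which makes "injected peak" well defined for recovery
experiments. HbO, HbR (opposite sign) and CBF share this time course.

Activation is a flat-top disk (radius 16 px on the default 128×128
field) with a Gaussian shoulder (σ = 4 px). A plateau rather than a
pure Gaussian was chosen deliberately: reported group-mean peak
amplitudes are ROI-averaged quantities, and averaging a region drawn
around the maximum of a *peaked* profile systematically understates the
nominal amplitude by 25–30 %, which would make "inject the group mean,
recover the group mean" internally inconsistent. With a plateau, the
ROI mean equals the nominal amplitude to within a few percent.

Group presets carry the study's group-mean amplitudes: control
offspring ΔHbO = 2.50, ΔHbR = −0.80, ΔCBF = +6.93 %; preeclamptic-line
offspring ΔHbO = 4.16, ΔHbR = −0.80, ΔCBF = +11.22 %. No HbR group
difference is modelled (none was observed); the −0.80 dip is a typical
venous-washout magnitude, about one third of the control HbO peak. The
concentration unit is an opaque label inherited from the extinction
table (see below).

**Reflectance channels** follow the forward modified Beer–Lambert
model, `R = R0·exp(−(ε_HbO ΔHbO + ε_HbR ΔHbR)·D)` with uniform
`R0 = 1000` counts. Camera noise is multiplicative Gaussian (relative
σ = 2 %, a shot-noise-like term) plus additive read noise (σ = 5
counts); at these defaults 7-block averaging yields clean traces, which
is the regime the protocol was designed for.

**The laser channel** draws per-pixel intensities from
`Gamma(1/K², μK²)` — the classical statistics of speckle integrated
over `1/K²` independent correlation cells — with the local contrast
enforced as `K = K0·sqrt(F0/F)`, `K0 = 0.3` at baseline flow. This is
by construction the exact inverse of the default `flow = 1/K²` map in
the flowmetry module, so flow recovery is a genuine round trip. As
flow → 0 (correlation time much longer than the exposure) K is capped
at the fully developed ceiling K = 1, where the Gamma law reduces to
the exponential intensity distribution.

What the generator does **not** emulate: photon-transport/partial
volume effects, vasculature (vessel exclusion in ROI selection is
implemented but exercised only via an optional dark-pixel heuristic),
heartbeat/respiration oscillations (the 0.3 Hz lowpass is kept anyway),
slow drifts, and spatially correlated speckle (pixels are independent;
real speckle grains span a few pixels, which mainly rescales the
effective number of independent samples per contrast window). Passing
recovery tests therefore demonstrates correctness of the estimators
under idealized noise, not robustness to every artifact of real data.

## Spectroscopy

Absorbance uses `ΔA = −log(R/R0)` by default so that darkening is
positive; a `sign="log"` switch reproduces the bare `log(R/R0)`
convention. The sign cancels in any forward/inverse round trip. `R0` is
the per-pixel temporal mean over a whole-run baseline window ending
0.5 s before the first onset; pixels with non-positive baseline are
masked and propagate as NaN rather than crashing.

The packaged extinction table (525/590/625 nm, rounded literature
whole-blood coefficients in mM⁻¹·cm⁻¹) fixes the concentration scale
and is user-overridable. The default differential pathlength factor is
0.005 cm at all wavelengths — an effective constant lumping true photon
pathlength and partial-volume dilution, chosen so that absorbance
excursions are of order 0.1–1 at the amplitude scale of the group
presets. Because the same `OpticalModel` defines both the forward
simulator and the inverse, `D` affects only the absolute concentration
label, never recovery accuracy. Users with calibrated pathlengths can
supply per-wavelength values.

Unmixing solves the 3-wavelength/2-chromophore system per pixel and
frame with the pseudo-inverse of `ε·D`, i.e. ordinary least squares;
rank deficiency raises an error naming the wavelengths. ΔHbT is the sum
of the two solutions, exactly.

## Speckle flowmetry

Spatial contrast is `σ/μ` over an odd sliding window (default 5×5,
community convention balancing resolution against estimator variance),
computed with reflection padding and the n−1 variance correction;
zero-mean windows are masked, constant regions give exactly K = 0. The
K→flow map is `1/K²` by default with an exposure-normalized variant
`1/(2TK²)`; both yield identical percent-change CBF since constants
cancel in the baseline ratio. The transform is applied pixelwise first
and ROI-averaged second. Contrast estimated from 25-pixel windows
carries a multiplicative bias of a few percent; it cancels in the
baseline-relative CBF because it is common to numerator and
denominator.

## Evoked-response extraction

* **Filter**: 4th-order Butterworth, 0.3 Hz, applied forward–backward
  (zero phase, unit DC gain). Filtering is applied to the ROI-averaged
  trace; by linearity this equals averaging filtered pixels.
* **ROI**: the localizer image is the mean stimulation-window frame
  minus the mean pre-stimulus frame. It is smoothed (Gaussian σ = 6 px)
  and thresholded at 0.6 of a robust maximum — the 99th percentile of
  the smoothed map — keeping the connected component containing the
  peak. The robust reference matters: flow maps derived from speckle
  contrast carry heavy, spatially correlated estimator noise, and a
  single-pixel maximum reference rides that noise, shrinking and
  off-centring the ROI. These defaults were calibrated on synthetic
  ground truth to transfer 96–100 % of the injected amplitude on both
  modalities. Manual masks are accepted for real data, where drawing
  around the response while avoiding vessels remains the norm; an
  optional dark-baseline percentile heuristic excludes large-vessel
  pixels from auto ROIs.
* **Epoching**: epochs span −4 s … stimulus offset + 2 s, aligned to
  the nearest sample of each realized (jittered) onset (±67 ms at
  7.5 Hz, negligible at 0.3 Hz bandwidth). Each block is re-baselined
  to its own mean over (−4, −0.5) s, then blocks are averaged. Blocks
  that do not fit in the recording are dropped with a warning; fewer
  than two survivors is an error.
* **Peak**: signed extremum within the stimulation window — maximum
  for HbO/HbT/CBF, minimum for HbR. The trial-averaged trace is the
  practical stand-in for an impulse response here: with 10 s blocks and
  40 s rests there is no overlap to deconvolve.

Residual estimator noise inflates the extremum slightly (max-of-noise
bias); at the default geometry this contributes ≲ +5 % to recovered
CBF peaks and is part of the recovery error budget quoted by the tests.

## Behavioral and physiological metrics

* Novel-object investigation ratio `t_novel/(t_novel+t_familiar)`;
  zero-exploration trials are unscorable and dropped with a warning.
* Water-maze probe metrics (target-quadrant time and distance, platform
  crossings) summarized per group with pooled t-tests; training-phase
  escape latencies compared per day (no repeated-measures model is
  invented beyond the per-day tests).
* Proteinuria as the albumin:creatinine ratio of duplicate-averaged
  readings; the common 1:10 dilution cancels and is only logged. The
  ratio is treated as unit-agnostic in the assay's concentration units.
* Pup weights averaged within litter first — the mother is the
  statistical unit — then summarized by maternal genotype.
* Two-group comparisons default to the pooled-variance independent-
  samples t-test (df = n₁+n₂−2, matching the `t(10)` reporting form at
  n = 6/group); Welch is available via `equal_var=False`.
* Synthetic novel-object cohorts draw per-animal ratios from a Beta
  distribution parameterized by the target mean and standard deviation
  (`sd = SEM·√n` when dispersion is reported as SEM), and total
  exploration time from a Gamma distribution (mean 30 s, shape 16 — a
  plausible 5-min-test exploration budget).

## Problem sizes and determinism

Recovery tests run the full protocol (7 jittered blocks, ~380 s at
7.5 Hz per channel). Imaging-scale ensembles use the 128×128 default
field for the headline recovery numbers and a 96×96 field (same
activation patch, hence same ROI statistics) for the routine 20-seed
pipeline property test; unit tests use 32–48 px fields with
proportionally smaller patches. All randomness flows through
`numpy.random.Generator` seeds; per-animal seeds are spawned from a
root `SeedSequence`, and identical seeds reproduce bit-identical frame
stacks and byte-identical summary CSVs.

## Known limitations

* The auto-ROI assumes a single connected activation; multi-focal
  responses would be truncated to the component containing the peak.
* Absolute concentration calibration depends entirely on the supplied
  extinction/pathlength table; defaults give self-consistent relative
  values, not oximetry.
* The speckle model is the simplified single-exposure `1/K²` regime;
  multi-exposure imaging and absolute flow calibration are out of
  scope.
* Masked (vessel/invalid) pixels propagate as NaN and are excluded from
  ROI averages; no inpainting is attempted.
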