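# Methods

## Background model and correction

Through-plane PC-CMR velocity images are contaminated by an additive,
spatially smooth velocity offset caused by eddy currents (and residual
Maxwell terms) — the "background phase". `pcflow` models it as a
polynomial surface in normalized, centered image coordinates
x, y ∈ [−1, 1]:

    order 1:  p(x,y) = a00 + a10·x + a01·y
    order 2:  p(x,y) = a00 + a10·x + a01·y + a20·x² + a02·y² + a11·xy

with coefficients in cm/s. Normalized coordinates keep the design matrix
well conditioned; the price is that coefficients are not comparable across
grid sizes, which every serialization records alongside the grid shape.

Estimation follows the stationary-tissue principle: pixels of stationary
chest-wall/mediastinal tissue have zero true mean velocity, so the
time-average of their measured velocity is an unbiased sample of the
background at that location. The correction stage

1. averages the velocity images over the cardiac cycle (one surface per
   series, not per-frame fits — averaging first suppresses pulsatile
   leakage and phase noise by √n_frames);
2. solves the unweighted ordinary least-squares problem
   min Σ_static (v̄ − p(x,y))² over the monomial basis. Weighting by
   magnitude was considered and rejected: the mask's magnitude gate has
   already removed the low-SNR pixels that weighting would down-weight;
3. subtracts the fitted surface from every frame (magnitude untouched).

The fit is performed on velocity (cm/s) rather than raw phase; the two
differ only by the constant factor VENC/π, so the formulations are
equivalent and one unit system suffices. A rank-deficient design (e.g. all
static pixels collinear) raises an error rather than silently
pseudo-inverting.

## Static-tissue mask

"Phase deviation" is implemented as the temporal standard deviation
(ddof 1) of a pixel's velocity across the cycle, thresholded in cm/s.
A pixel enters the mask iff

* temporal SD ≤ the phase-deviation threshold (default 2 cm/s),
* time-averaged magnitude ≥ 0.3 × the image's median time-averaged
  magnitude (scanner magnitude units are arbitrary, so the gate is
  relative), and
* it lies outside every exclusion ROI and every vessel ROI. Vessels are
  excluded unconditionally; lungs are excluded by ROI because their phase
  is pure noise (phase noise scales inversely with magnitude SNR).

`maximize_static` reproduces the interactive clinical workflow of raising
the phase-deviation threshold until enough static tissue is included: the
threshold grows geometrically (factor 1.25) from its starting value until
the mask covers 30% of the grid or a 25 cm/s ceiling is reached. This is
what the pipeline uses, because the adaptive VENC (below) changes the
noise floor between subjects.

Point-in-polygon tests use the even-odd rule with boundary points counted
as inside; polygons are rasterized at pixel centers.

## Flow quantification

Flow through a fixed ROI is Σ_ROI v · pixel-area (cm/s × cm² = ml/s),
integrated by the rectangle rule with uniform frame duration
R-R/n_frames (retrospective gating). Forward/backward volumes integrate
the positive/negative per-frame flows separately; net = forward − backward
holds exactly. The ROI is fixed across frames — adequate for rigid
synthetic vessels, a documented simplification for real, moving anatomy.

Qp/Qs = PA net volume / aortic net volume. Classification uses the normal
range 0.9–1.2 with *inclusive* bounds (the range is stated without
boundary language anywhere; inclusivity is the package's fixed choice);
above → left-to-right shunt, below → right-to-left. The eligibility filter
excludes a subject when the sample SD of the beat-to-beat R-R intervals
exceeds 10% of their mean in any acquisition ("exceeds" strict, so exactly
10% remains eligible). BSA uses DuBois & DuBois,
0.007184·W^0.425·H^0.725 (kg, cm → m²).

## Synthetic phantoms

One phantom emulates a through-plane acquisition at the great vessels on a
96×96 grid, 2 mm pixels, 30 frames over a 1000 ms cycle:

* **vessels** — ascending aorta (radius 14 mm) and main pulmonary artery
  (13.5 mm) as circular cross-sections with a spatially parabolic,
  temporally pulsatile profile: a half-sinusoid systolic ejection over the
  first 40% of the cycle plus a 5% constant diastolic component, peak
  scaled so the discrete cycle integral equals the target stroke volume
  exactly. Vessel membership is pixel-center-in-circle with no
  partial-volume weighting, and the flow stage integrates the identical
  pixel set — so noise-free, background-free recovery is exact to float
  precision and every background-induced error is attributable;
* **static tissue** — everything else inside the body, magnitude 1.0,
  velocity 0;
* **lungs** — two lateral ellipses with magnitude reduced by
  snr_lung/snr_tissue (default 3/30), hence ten-fold noisier phase;
* **background** — an order-0/1/2 polynomial added to every frame;
* **noise** — independent Gaussian velocity noise with
  SD = VENC/(π·SNR·m_rel), m_rel the local relative magnitude: the
  standard reciprocal-SNR phase-noise law. Default tissue SNR is 30
  (free-breathing with three-fold averaging), giving σ ≈ 1.6 cm/s at
  VENC 150 — consistent with the default 2 cm/s mask threshold admitting
  ~97% of static pixels. Magnitude images receive 1/SNR Gaussian noise.

Aliasing (any noise-free |v| > VENC) and geometric overlap are rejected
with explicit errors. `adapt_venc` mimics the clinical protocol step of
choosing VENC per acquisition: the lowest of {100, 150, 200, 250, 300}
cm/s that clears the implied peak velocity plus worst-case background with
5% headroom.

An exact **bias law** follows from linearity: adding background b(x,y) to
every frame changes a vessel's measured net volume by exactly
pixel-area × R-R × Σ_vessel b. Tests verify it against brute-force
summation, and it is also what makes fast cohort-level Monte-Carlo
calibration possible.

## Synthetic cohorts

A cohort draws, per subject: true Qp/Qs ~ N(1.0, 0.04) truncated to
(0.5, 2.0) (shunt-free spread); aortic stroke volume ~ N(93, 22) ml
truncated to (40, 180); sex/age/weight/height covariates with typical
adult clinical moments. Each subject contributes two acquisitions (aorta
plane, PA plane), matching clinical practice, and each acquisition gets an
independent order-2 background with i.i.d. N(0, σ) coefficients.

σ is the one deliberately calibrated constant: it was set so that ≈18% of
*uncorrected* Qp/Qs ratios fall outside 0.9–1.2 — the clinically observed
prevalence of spurious out-of-range ratios the correction is meant to fix.
Monte-Carlo over 50 seeds using the exact bias law gave mean out-of-range
fractions of 0.172 at σ = 0.95 cm/s and 0.186 at σ = 1.0 cm/s;
σ = 0.98 cm/s (≈ 0.180) is frozen as `DEFAULT_BACKGROUND_COEFF_SD`. At
that setting a typical per-acquisition offset at a vessel is ~1 cm/s —
physically plausible for uncorrected eddy-current offsets at 1.5T.

What the simulator does **not** emulate: k-space acquisition and coil
sensitivities, partial-volume edges, vessel motion/through-plane
compliance, respiratory drift, arrhythmic beat-to-beat flow variation
(the R-R series only feeds the eligibility filter), phase wrap-around, and
concomitant-gradient structure in the background (the offset is exactly
polynomial, so a matched-order fit can be exact). Passing tests therefore
demonstrate correctness of the estimation machinery and realistic behaviour
under noise — not performance on real scanner data, where the background
is only approximately polynomial and the static mask is imperfect.

## Statistics

* **McNemar** — exact two-sided binomial on the discordant counts:
  p = min(1, 2·P(X ≤ min(b,c))), X ~ Bin(b+c, ½); p = 1 with no
  discordance. The exact version is well defined at the small discordant
  counts these cohorts produce, where the χ² approximation is unreliable.
* **Variance comparisons** — F-test (two-sided, s²x/s²y) for normal data;
  otherwise "non-parametric Levene": the pooled data are rank-transformed
  and the median-centered Levene (Brown-Forsythe) statistic on the ranks is
  referred to F(1, n−2).
* **Normality gate** — one-sample Kolmogorov-Smirnov against a normal with
  the sample's own mean/SD, α = 0.05 (the estimated-parameter variant used
  by clinical statistics software; conservative). The gate routes F-test vs
  rank Levene and t-tests vs rank location tests.
* **ICC** — two-way, absolute-agreement, single-measure:
  (MSR − MSE) / (MSR + (k−1)MSE + k/n(MSC − MSE)), unclamped (negative
  values are informative anti-agreement).
* **Covariate screen** — each covariate split at its median (ties to the
  low group; deterministic), spread of corrected Qp/Qs compared between
  groups with the gated variance test, significance at α/m with m = 20,
  i.e. p < 0.0025; groups under 3 subjects are skipped with a warning.
* Reported percentages are rounded to integers, as clinical tables print
  them.

## Problem sizes and numerical choices

The test suite and acceptance script use 96×96×30 phantoms, 91-subject
cohorts, 50-seed Monte-Carlo for calibration checks and the cohort
demonstration, 1000-rep null simulations for test calibration, and 100
random instances for the normal-equation and ANOVA oracles — sizes chosen
so a complete run finishes in a few minutes on one CPU while leaving
Monte-Carlo standard errors well inside the asserted margins. Fits use
`numpy.linalg.lstsq` with explicit rank checking; equality-critical
comparisons (ground-truth recovery, bias law, oracle equivalence) assert
at 1e-8–1e-12 relative tolerance; stochastic assertions state their
margins explicitly (e.g. type-I error ≤ 6% at nominal 5% over 1000 reps).

## Known limitations

* Exactly polynomial backgrounds make the matched-order fit an upper bound
  on real-world performance; the cohort demonstration is a controlled
  analogue, not a clinical reproduction.
* The DICOM ingestion path covers the common magnitude/phase pair layout
  with rescale tags and an explicit VENC; vendor-private VENC tags and
  interleaved multi-slice layouts are out of scope.
* No phase unwrapping: aliased inputs are rejected, not repaired.
* The fixed ROI and rigid vessels ignore in-plane motion and partial
  voluming present in real acquisitions.
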