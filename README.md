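# pcflow

Stationary-tissue background phase correction and Qp/Qs shunt
quantification for phase-contrast cardiovascular MR (PC-CMR), with a
synthetic phantom/cohort simulator and the cohort precision statistics
needed to evaluate the correction.

## The problem

PC-CMR encodes through-plane blood velocity in the image phase. Eddy
currents from gradient switching add a spatially smooth spurious phase —
a velocity offset of order 1 cm/s that varies slowly across the image.
Integrated over a vessel cross-section and a cardiac cycle, that small
offset shifts measured stroke volumes by several ml, and therefore shifts
the pulmonary-to-systemic flow ratio Qp/Qs, the screening measurement for
intracardiac shunts (normal range 0.9–1.2; above it left-to-right shunt,
below it right-to-left).

Stationary-tissue background correction estimates the offset from the
patient's own chest-wall tissue: stationary pixels have zero true mean
velocity, so a surface fitted through their time-averaged velocity *is*
the background. `pcflow` implements the full workflow:

1. **simulate** — velocity-encoded cine phantoms (two circular vessels
   with pulsatile parabolic flow, static tissue, noisy lung fields, a
   known polynomial background) and whole cohorts, with exact ground truth;
2. **mask** — static-tissue detection by a phase-deviation (temporal SD)
   threshold and a relative magnitude gate, with polygon exclusion ROIs and
   mandatory vessel exclusion;
3. **correct** — ordinary least-squares fit of a first- or second-order
   2D polynomial `p(x,y) = a00 + a10·x + a01·y [+ a20·x² + a02·y² + a11·xy]`
   (normalized coordinates x, y ∈ [−1,1], cm/s) to the time-averaged
   velocity of masked pixels, subtracted from every frame;
4. **flow** — ROI flow curves (Σ v·pixel-area, ml/s), net/forward/backward
   volumes by rectangle-rule integration over the R-R interval, Qp/Qs and
   its classification, the R-R variability eligibility filter, DuBois BSA;
5. **stats** — exact McNemar on paired before/after classifications,
   F-test / rank-based Levene variance comparisons routed by a
   Kolmogorov-Smirnov normality gate, absolute-agreement single-measure
   ICC, median-dichotomized covariate screens with Bonferroni control
   (α/m = 0.05/20 = 0.0025), and 2×2 reclassification summaries;
6. **pipeline/CLI** — the end-to-end cohort experiment with deterministic
   reports.

## Worked example

```
pcflow run --seed 1 --out out/
```

runs a 91-subject synthetic cohort (true Qp/Qs ~ N(1.0, 0.04); each
acquisition carries an independent quadratic background offset with
coefficient SD 0.98 cm/s) and prints:

```
pcflow cohort report
====================
subjects: 91  seed: 1
true Qp/Qs ~ N(1.0, 0.04) truncated to (0.5, 2.0)
static-mask thresholds: phase SD <= 2.0 cm/s, magnitude >= 0.3 x median
normal Qp/Qs range: 0.9-1.2 (inclusive)

out-of-range fraction, uncorrected: 0.165
out-of-range fraction, linear: 0.044
  linear: pathological 16% -> 4%, normalized 100% of initially pathological, exact McNemar p = 0.01921 (b=15, c=4)
out-of-range fraction, quadratic: 0.000
  quadratic: pathological 16% -> 0%, normalized 100% of initially pathological, exact McNemar p = 6.104e-05 (b=15, c=0)
...
```

Reading this: with uncorrected measurements, 16% of shunt-free subjects
fall outside the 0.9–1.2 normal range purely because of background offsets;
subtracting a fitted linear surface reduces that to 4%, and a quadratic
surface (matching the simulated offset order) to 0%. The exact McNemar
p-values test the paired change in classification (b = subjects normalized,
c = newly pathological). Per-subject results land in `out/cohort_table.csv`
and machine-readable summaries in `out/summary.json`.

The individual stages are available as `pcflow simulate / mask / correct /
quantify / cohort-eval`, and everything is importable from the library
(`pcflow.make_phantom`, `pcflow.detect_static`, `pcflow.fit_background`,
`pcflow.qpqs`, ...).

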