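# Methods

This note documents the models, parameter choices and numerical decisions
behind `vcgmi`, and what the synthetic cohorts do and do not establish
about behavior on real recordings.

## Signal model and preprocessing

Records are three synchronized orthogonal leads in mV at a common
sampling rate (1 kHz for PTB-style recordings). The only preprocessing is
baseline-wander removal: each lead's baseline is estimated by a
second-order Savitzky–Golay local-polynomial smooth with a 1201-sample
window and subtracted. Two decisions here were genuinely open:

- **Cutoff formula.** For a second-order SG smoother the approximate
  −3 dB point is taken as `f_c = fs / (2·window)`; at (1201, 1 kHz) this
  is 0.41632 Hz, printed as ≈0.416 Hz. The polynomial order does not
  enter this approximation. A formula involving the order would change
  the printed value; this reading is the one consistent with treating the
  smoother as a moving least-squares low-pass of width `window`.
- **Edge handling.** Near the record borders the polynomial fitted to the
  first/last full window is evaluated at the edge samples
  (`scipy.signal.savgol_filter(mode="interp")`). This avoids the
  zero-padding transients of reflective or constant padding, and is a
  vectorized alternative to refitting a truncated window at every border
  sample; the two differ only inside the outer 0.6 s and neither affects
  the stated invariants (exact additivity of baseline + detrended signal,
  linearity, exact reproduction of polynomial trends).

The filter deliberately does nothing else: no power-line notch, no
high-frequency denoising.

## Delineation

Beat detection is a deliberately simple stand-in, since loop features —
not delineation — are the subject: R peaks are local maxima of the
spatial magnitude exceeding 0.5× a rolling 2 s maximum, with a 200 ms
refractory period. Loop windows are fixed physiologic durations: QRS =
R ± 60 ms; T = [R + 120 ms, R + min(450 ms, 0.7·RR)], using the RR to the
next beat (median RR for the last beat). Beats whose windows cross a
record boundary or whose RR < 300 ms are dropped and counted in a log
line. All constants are exposed in `DelineationConfig`. No separate
T-peak detection is attempted; T-window maxima are taken over the whole
window.

## Loop features

For one loop (an ordered set of 3D points), the *optimal plane* is the
least-squares plane through the points: centroid = point mean, axes =
right singular vectors of the centered point matrix, with the first two
spanning the plane. Projection coordinates are the first two principal
components. Numerical notes, each a deliberate reading of an ambiguous
convention:

- **Arc length** sums consecutive Euclidean steps of the projected curve
  and does *not* close the loop: it is a discrete curve integral over the
  traced samples.
- **Area** is the unsigned shoelace sum over consecutive projected
  vertices *with* closure (last vertex paired with the first): a polygon
  area. For a self-intersecting (figure-eight) loop this is the absolute
  signed area, not the geometric enclosed area; this is documented
  behavior, not a bug.
- **Maximum vector** is computed literally as
  `√(max X² + max Y² + max Z²)` with per-lead maxima taken independently
  over the window. The maxima need not be simultaneous, so this can
  exceed the largest point norm and is *not* rotation-invariant; a
  `strict_max_norm` option computes `max ‖point‖` instead for users who
  want the frame-independent variant.
- **Velocity** is the forward-difference step length times the sampling
  rate (mV·s⁻¹, sampling-rate independent), with max, mean and
  *population* standard deviation reported. Velocities are measured on
  the raw 3D windows, not the projections.
- **areaT** uses the T loop's own optimal plane, fitted independently of
  the QRS plane.

Per-beat vectors are aggregated to one record vector by the per-feature
**median** (a `mean` option exists). The median is robust to the outlier
beats that the screening stage deliberately keeps.

## Screening

Per feature: Shapiro–Wilk p on the pooled sample (headline column) and
per class; two-sided Mann–Whitney U between MI and HC. The exact U null
distribution is enumerated when `n_a·n_b ≤ 400` and the pooled sample is
tie-free; otherwise the normal approximation with tie and continuity
corrections is used. Features are ranked by ascending p (ties broken by
name). α = 0.05; no multiple-testing correction is applied across the 12
features, and screening never drops a feature — it is descriptive.
Boxplot summaries use linear-interpolation ("type 7") quartiles with
Tukey fences at 1.5·IQR; fence-crossing observations are listed and
retained, because extreme loop morphologies are real clinical data.

## Classifier grid

210 configurations across nine families, in fixed enumeration order:
DT 32 (2 split criteria × min-leaf {2,4,8,16} × max-splits {5,10,20,50}),
SVM 25 (poly-2/3/4, linear, RBF × kernel scale 1–5), KNN 36 (K
{5,10,15,20} × Euclidean/city-block/Chebyshev × equal/inverse/squared-
inverse vote weighting), DA 6 discriminant types, ANN 20 (16 two-layer +
4 one-layer sizes over {5,10,20,50}), NB 10 (2 priors × normal/kernel ×
4 kernel shapes), RF 25 (trees 100–500 × min-leaf 1–5), LR 24 (2 priors ×
lasso/ridge × 6 solvers; the 16 solver/penalty combinations that are not
supported are enumerated but flagged, and evaluate to an explicit
unsupported result rather than an exception), EM 32 (AdaBoost, robust
boosting, random-undersampling boosting × tree/discriminant learners,
plus LogitBoost and GentleBoost with tree learners, × 50–200 cycles).

Base learners are scikit-learn estimators behind the grid surface. Where
a grid variant has no direct scikit-learn equivalent, the nearest
standard algorithm stands in, implemented here where necessary:

| grid entry | implementation |
|---|---|
| kernel scale *s* (SVM) | features divided by *s* before the kernel; poly kernels use `coef0 = 1` |
| SVM class scores | logistic map of the decision margin (monotone, deterministic; no internal calibration folds) |
| squared-inverse KNN weights | custom weight callable `1/d²` (zero distances take all weight) |
| diag-linear / diag-quadratic DA | `DiagonalDiscriminant` — Gaussian discriminant with pooled / per-class diagonal covariance |
| pseudo-linear / pseudo-quadratic DA | LDA with least-squares solver / QDA with small covariance regularization |
| kernel Naive Bayes | `KernelNaiveBayes` — per-feature product KDE with Silverman bandwidth; normal, box, Epanechnikov and triangle kernels |
| LR solvers | sgd → `SGDClassifier` (log loss); sparsa → saga with l1; bfgs/lbfgs → lbfgs with l2; "uniform prior" → balanced class weights |
| robust boosting | AdaBoost with shrinkage (learning rate 0.5) |
| RUS boosting | one random undersampling of the majority class, then AdaBoost |
| LogitBoost / GentleBoost | gradient boosting of stumps with log / exponential loss |
| discriminant boosting learners | `ResampleWrapper` adds sample-weight support by weighted bootstrap resampling |

Every configuration is evaluated with stratified 10-fold CV;
standardization (center/scale) is fitted on the nine training folds only.
Scores are MI-class probabilities; hard labels use threshold 0.5. KNN's
neighbor count is capped at the training-fold size so large-K rows remain
runnable on small cohorts. All stochastic estimators receive seeds
derived from one master seed.

## Stacking protocol

The meta-feature matrix holds each base model's out-of-fold scores under
the shared fold plan — continuous scores, not hard labels, since scores
strictly generalize labels. The logistic-regression meta-classifier is
evaluated fold-wise on that matrix: for each fold it is refitted on the
other folds' OOF rows and scores the held-out fold. A fully nested
protocol (recomputing base OOF matrices inside every outer fold) would
multiply base-model fits roughly tenfold; the shared-plan reading is the
standard leakage-safe construction in which no sample's stacked score
ever depends on a base or meta model trained on that sample's fold, and
it is the one implemented. The default base set is the nine per-family
reference configurations; `select_best_per_family` re-derives the set
from grid results by CV accuracy (ties broken by higher sensitivity,
which is clinically preferred for MI detection).

## Metrics

MI is the positive class. Sensitivity, specificity, accuracy, PPV, NPV
and f1 follow the usual count ratios; any metric with a zero denominator
is reported as undefined (`None`), never silently 0 — with few controls
per fold, empty confusion cells happen. Percentages render with two
decimals. ROC curves sweep the distinct scores; AUC is the trapezoid rule
and equals the Mann–Whitney probability-of-correct-ranking with midpoint
tie handling. The default operating point maximizes Youden J = TPR − FPR,
with exact ties broken toward higher sensitivity; a
closest-to-top-left criterion is available.

## Synthetic cohorts

The generator produces what the features measure and nothing more. Each
record is a beat train at 1 kHz: per beat, the QRS loop is a planar
ellipse (half-axis ratio 0.5) in a plane drawn at random per record; the
ellipse center is offset along the major axis by exactly the major
half-axis, so the loop starts and ends at the origin (no step against the
baseline) and the spatial magnitude has a unique maximum at the window
center — the ground-truth R peak. The T loop is a smaller ellipse in the
same plane centered at R + 280 ms. Class effects are constructed to
mirror the infarction signature: MI QRS half-axes scale by
`√mi_qrs_area_scale` (area scales by exactly `mi_qrs_area_scale`,
default 0.5) and the MI T loop is traced over a duration stretched by
`1/mi_t_velocity_scale` (speed scales by exactly the factor, default 0.6,
with loop geometry — hence areaT and maxVecT — unchanged).

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| fs, duration | 1 kHz, 10 s | PTB-style rate; ~10–13 beats/record |
| heart rate | 60–80 bpm | resting sinus range |
| QRS half-axis | 1.2 mV | R magnitude 2·a = 2.4 mV, upper physiologic range |
| T half-axis, duration | 0.35 mV, 160 ms | T/R amplitude ratio ~0.3; keeps the slowed MI T loop inside the ST-T window and below the R-detector threshold |
| wander | 0.3 mV at 0.15 Hz | respiration band, below the 0.416 Hz cutoff so detrending removes it |
| white noise | 5 µV SD | residual post-acquisition noise; forward-difference velocity amplifies noise by `fs·√6`, so the ~12 mV/s noise floor must not bury the T-velocity contrast |
| QRS size spread | 22 % (log-normal, per record) | between-subject anatomy; spreads all QRS-size features so their rank statistics do not saturate |
| T size spread | 5 % (log-normal, independent) | repolarization amplitude varies less in this idealized cohort, keeping the constructed T-velocity contrast the dominant discriminator, as in the motivating data |
| beat jitter | 3 % on radii and RR | exercises per-record aggregation |

What the cohorts do **not** emulate: P waves, non-planar or non-elliptic
loops, ST-segment shifts, conduction defects, arrhythmia, electrode
artifacts, colored noise, or any 12-lead structure. Passing tests on
synthetic cohorts therefore establish that the pipeline recovers loop
geometry and constructed class effects under wander and noise — they say
nothing about delineation robustness or effect sizes on clinical
recordings, where beat segmentation is the dominant unknown.

## Problem sizes

The test suite and examples run cohorts of 40 + 40 records of 10 s
(pipeline recovery, screening) and 6–12 records for unit-level checks;
statistical oracles use 1000-repetition simulations at two-sample sizes
of 40 per group. These sizes give the rank tests and cross-validated
accuracies enough resolution for the assertions made while keeping the
whole suite in the tens of seconds.

## Known limitations

- Beat delineation is a fixed-window stand-in; clinical use would swap in
  a validated delineator behind `DelineationConfig`.
- The MATLAB-specific boosting variants and discriminant flavors are
  mapped to nearest standard algorithms (table above); per-configuration
  metrics are therefore comparable but not bit-identical to environments
  implementing the original variants.
- The literal per-lead maximum-vector feature is frame-dependent by
  construction; cross-device comparisons should consider
  `strict_max_norm`.
- Class imbalance is handled only through the prior/class-weight
  parameters of the families that expose one; no resampling is applied.
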