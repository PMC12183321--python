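# Methods

This note documents the models, numerical choices and limitations of
`glucopheno`.  Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Metabolic measures

**C-peptide deconvolution.**  C-peptide is co-secreted with insulin but not
hepatically extracted, so the prehepatic insulin secretion rate (ISR) is
recoverable from peripheral C-peptide.  We use the classic two-compartment
population model: plasma compartment C1 with irreversible elimination k01
and exchange (k21 out / k12 back) with a peripheral compartment C2, central
volume V.  Population parameters are stored per clinical class as the
fraction and half-lives of the biexponential bolus response — normal
0.76 / 4.95 min / 33.5 min, obese 0.78 / 4.55 / 33.3, type-2-diabetic
0.78 / 4.52 / 34.8 — and converted to rate constants through the standard
identities (k12 = F·b + (1−F)·a, k01 = a·b/k12, k21 = a+b−k01−k12 with
a, b the fast/slow rate constants).  The class rule: diabetic if fasting
glucose > 126 mg/dl, 2-h glucose > 200 mg/dl or HbA1c > 6.5%; otherwise
obese if BMI > 30; otherwise normal.  The central volume defaults to
3.0 l per m² of DuBois body surface area (≈5.4 l for a 1.8 m² adult) and
is configurable; none of the pipeline's contracts depend on its exact
value because generation and inversion share the same parameters.

The inverse problem is solved as non-negative, second-difference
(Tikhonov) regularized weighted least squares over piecewise-constant
15-min secretion blocks on [0, 180] min.  Weights are the measurement SDs
implied by the error coefficient of variation (default 5%); the
regularization weight is chosen by bisection under the discrepancy
principle so the fit's residual CV approaches the error CV from below.
The basal steady state implied by the fasting sample (S_b = k01·V·C_0) is
subtracted analytically, and incremental block rates are bounded below by
−S_b so total secretion stays non-negative.  Rates are reported per kg of
body weight.  Round-trip accuracy (forward-simulate a known rate,
deconvolve) is tested to <10% relative RMSE with the error CV matched to
the (noise-free) input; with 5% multiplicative noise the 7-point sampling
supports qualitative, not pointwise, recovery — which is all the
disposition index needs, since it integrates the first 30 minutes.

**Disposition index.**  DI = trapezoid ∫₀³⁰ ISR dt / SSPG, units
(pmol·dl)/(kg·ml).  SSPG (steady-state plasma glucose from the
insulin-suppression test) is an input; the wet-lab procedure is out of
scope.

**Incretin effect.**  IE% = 100·(AUC_OGTT − AUC_IIGI)/AUC_OGTT over
trapezoid C-peptide areas on [0, 180] min.  IE may be negative and never
exceeds 100; it is invariant to rescaling both series.

**Hepatic IR index.**  The published regression surrogate with natural
logarithms (the convention of its source publication): −0.091 +
0.4·ln(insulin AUC 0–180) + 0.346·ln(BF%) − 0.408·ln(HDL) + 0.435·ln(BMI).
Body fat is the Deurenberg estimate.  The ternary bands are
IS < 3.95 ≤ intermediate ≤ 4.8 < IR; the published caption's "IS when
index > 3.95" contradicts its own intermediate band and is treated as a
typo for "<", configurably.

**Thresholds.**  Binary cut-points (SSPG 120, DI 1.58, IE 53.38%, hepatic
4.35) are the reference cohort's 50th percentiles and are configurable.
Boundary convention: values exactly at a cut are assigned to the
non-dysfunction side, except SSPG where ≥120 counts as resistant — the
stricter of the two wordings in the source material.

**HOMA / Matsuda.**  Glucose in mg/dl, insulin in µIU/ml: HOMA-IR =
G·I/405, HOMA-B = 360·I/(G−63) (undefined at G ≤ 63, returned as NaN with
a warning), Matsuda = 10000/√(G₀·I₀·Ḡ·Ī) with Ḡ, Ī trapezoid
time-weighted means over the 0–120-min OGTT samples (the source does not
restate the formula; this is the standard composite form).

## Deviance subphenotyping

Deviance = (x − mean)/sd per measure, after negating DI and IE so positive
always means more abnormal.  The SD uses the sample (n−1) denominator,
exposed as `ddof`.  Dominance: with sorted deviances d1 ≥ d2 ≥ d3 ≥ d4 and
gap δ = 0.5, dominant if d1−d2 ≥ δ; co-dominant (top two) if d1−d2 < δ ≤
d1−d3; otherwise unclassified.  Exact ties at the top are co-dominant
(gap 0 < δ); a gap exactly equal to δ counts as dominant.  Participants
missing any measure are excluded from cohort statistics, not imputed.

## Curve features

Integrals, peak search and slopes are defined on [0, 180] min with G_0 as
baseline; the −10-min pre-load sample enters only the CV, which is the
sample SD over mean of all 16 values.  The incremental decomposition is
the standard one relative to baseline — pAUC/nAUC are the areas of the
positive/negative parts of g − G_0 and iAUC = pAUC − nAUC, so
AUC = iAUC + 180·G_0 exactly.  CurveSize is the polyline arc length in
mixed units (min, mg/dl), computed on raw units without rescaling.  Peak
ties break to the earliest time so T_baseline2peak is well defined;
S_baseline2peak is 0 when the peak is at t=0, S_peak2end 0 when at t=180.
Missing samples are linearly interpolated in time; leading/trailing gaps
take the nearest observed value.

## Reduced representation

Per-curve Z-normalization removes amplitude so only shape remains;
a cubic smoothing spline then suppresses sample noise.  The smoothing
parameter uses a normalized convention s ∈ [0, 1] — 0 interpolates, 1
degenerates to the least-squares line — mapped to the penalized-spline
weight λ = s/(1−s) · mean(Δt)³ (the Δt³ factor makes s roughly
grid-invariant).  The published analysis names the value 0.35 but not the
convention; the convention is therefore configurable, and the
reference-data PCA regression arbitrates it when the deposited series are
available.  PCA uses mean-centring only (inputs are already per-curve
normalized); loadings are sign-fixed by forcing each column's
largest-magnitude element positive, making scores reproducible.  The basis
(mean vector, 16×2 loadings W) is fitted on training curves only and
held-out curves are projected as (x − mean)·W; inside the cross-validation
this refit happens per training fold via the sklearn Pipeline, which is
what rules out leakage.

## Classifier benchmark

Architectures: L1-penalized logistic regression (SAGA solver, iteration
cap 10 000), linear-kernel SVM, RBF-kernel SVM, random forest.
Hyperparameter grids (the published protocol states five values per model
without listing them): C ∈ {0.01, 0.1, 1, 10, 100} for the SVMs and the
logistic model, tree count ∈ {50, 100, 200, 400, 800}; both overridable.
Every pipeline standardizes features before the classifier — a numerical
choice of this package (unscaled mixed-unit covariates stall SAGA and
distort the RBF kernel).  Scores for auROC are decision-function margins
for the SVMs and class-1 probabilities for the logistic and forest models;
no probability calibration.  Cross-validation is stratified k-fold
(k = 5), reshuffled each repeat (100 repeats in the full protocol;
desk-scale runs use fewer — the acceptance script uses 3 — because the
selection gap it demonstrates is large).  Hyperparameter tuning and model
selection are merged in the same CV loop, reproducing the published
protocol; the resulting optimism of the selected model's CV score is the
known cost of that merge and is why held-out test metrics are also
reported.  Selection is by mean CV auROC (ties to the simpler model);
the alternative lexicographic (F1, sensitivity) ordering used for
reporting is available.  Feature-set comparisons use the two-sided
Wilcoxon rank-sum test on CV auROC distributions with Bonferroni
adjustment.

Permutation nulls are averaged over several independent label
permutations: any single permutation retains a chance sample-level
association with the features that generalizes across folds of the same
dataset, so one permuted run can sit 0.1 away from 0.5 while the
permutation-averaged null centres there.

## Synthetic cohort generator

The generator defines the study conditions for all desk-scale checks.

*Latent state.*  Four severities (muscle IR, beta-cell deficiency,
incretin deficiency, hepatic IR) from a Gaussian copula with correlations
0.7 (muscle–hepatic), 0.6 (muscle–beta), 0.2 elsewhere, mirroring the
pairwise structure reported between the measured axes.  A shared loading
(0.25) on standardized BMI ties insulin resistance to adiposity; the
residual copula is adjusted so the target correlations are preserved
exactly (verified empirically to ±0.05 at n = 5000).  Marginals: SSPG =
132 + 52·z clipped to [40, 300] mg/dl (the observed range of the reference
cohort); beta capacity = exp(−0.5·z); incretin fraction =
logistic(0.135 − 0.85·z), giving a median near 0.53.

*Covariates.*  Age ~ N(55, 10); BMI ~ N(26, 5) truncated to the
eligibility window [23, 40] (truncated mean ≈ 28.3); balanced sex; HDL ~
N(60, 22) floored at 20; fasting glucose ~ N(98, 14) truncated to
[65, 160] so HOMA-B stays defined for every participant; fasting insulin
log-normal with mean 10 µIU/ml; HbA1c ~ N(5.6, 0.4); a polygenic score
built to correlate ≈0.5 with HbA1c.

*Glucose curves.*  G(t) = G0 + A·(t/τ)^k·exp(k(1−t/τ)) for t > 0 (peak A
at t = τ, k = 2.2), a smooth unimodal kernel reproducing mono-phasic OGTT
shapes; bi-phasic curves are out of the generator's scope.  G0 = 88 +
4·z_hep + 2·z_muscle; A = 58 + 14·z_muscle + 8·z_incretin + 6·z_beta;
τ = 42 + 8·z_beta + 4·z_muscle (so beta-cell deficiency raises 2-h
glucose through slower decay).  Additive assay noise SD 2.5 mg/dl; the
−10-min point is G0 plus noise.  These defaults were calibrated once so
the synthetic cohort medians of DI, IE and the hepatic index land near the
reference cut-points (1.58, 53.38, 4.35); the acceptance script reports
the realized medians.

*C-peptide.*  Oral secretion = basal + 0.155·capacity·excursion
pmol/kg/min, pushed through the same kinetic model used for inversion
(matrix-exponential stepping on a 5-min grid).  Basal plasma C-peptide is
650·exp(0.25·z_muscle + 0.125·z_hep) pmol/l.  The isoglycaemic IV test is
modelled as an exact (1 − ie)-rescaling of the whole oral response,
including basal secretion and initial state — an idealization (fasting
C-peptide is really test-invariant) adopted so the measured AUC-ratio IE
identifies the programmed fraction exactly, which pins the
forward/inverse contract.  Multiplicative noise CV 4%.

*Insulin.*  Fasting level times (1 + 0.045·excursion), scaled by
exp(0.5·z_hep + 0.25·z_muscle) and a global factor 1.55 so the hepatic
index has realistic location and spread; noise CV 6%.

*CGM.*  Each home test interpolates the plasma curve to 5-min sampling,
applies a 5-min sensor lag, white sensor noise (SD 7 mg/dl — no noise
model is published, so this is a package default), and a per-test level
shift whose SD is calibrated analytically (via the c4 small-sample SD
bias constant and the harmonic-mean glucose level) so the expected
between-test CV per timepoint matches the 11% target.  One global seed;
per-participant streams are split counter-style (SeedSequence spawn keys),
so growing a cohort never reshuffles existing participants.

*What the generator does not emulate:* bi-phasic and multi-peak glucose
curves, assay drift, CGM compression/pressure artefacts and dropout runs,
ethnicity- or age-dependent physiology, and measurement error in SSPG
beyond a small assay term.  Passing desk-scale checks therefore
demonstrates correctness of the machinery under the programmed structure,
not clinical performance on real cohorts.

## Problem sizes

Desk-scale defaults: unit tests run cohorts of 12–60 participants;
cohort-scale statistical checks use 1000–8000 draws of the cheap samplers;
the benchmark checks use n = 200 with 3–10 CV repeats.  These sizes were
chosen to make the statistical contracts sharp while keeping the whole
suite fast to iterate on.

## Known limitations

- The deconvolution prior (second-difference penalty with discrepancy
  stopping) is a standard choice; other regularizations would return
  slightly different pointwise ISR, though DI is insensitive because it
  integrates 30 minutes.
- Whether ISR should be normalized per kg or per body-surface area is not
  settled by the DI unit alone; per-kg is used, with weight an explicit
  argument.
- CV auROC from the merged tuning/selection loop is optimistic; use the
  held-out columns of the benchmark table for unbiased estimates.
- The reference-data regressions (dominance partition 16/13/3, cut-point
  medians, PCA variance fractions) require the study's deposited tables
  under `data/reference/` and fail with an explanatory message when those
  are absent.
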