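# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that make results reproducible.

## Study design emulated by the generator

The synthetic experiment mimics a potted-plant manipulation: pots of tea
plants caged with leafhopper nymphs at nominal densities of 0, 0.5, 1,
1.5 or 2.0 insects per young leaf, scored after a short feeding bout for
final insect density, percent damaged leaf area per leaf (from scanned
images), and metabolite profiles.

Defaults (`SyntheticConfig`):

* `n_pots = 19`, density levels cycled over the five treatments.
* **Density jitter** ±0.25 insects/young leaf (uniform, truncated at 0):
  final densities drift from nominal treatments because insects die
  during transfer or hatch from eggs already on the plants. Jitter also
  guarantees distinct predictor values, which the change-point candidate
  grid needs.
* **Damage model**: `ln(mean % damage) = ln(2.0) + 1.2·max(0, d − 0.6) + ε`,
  `ε ~ N(0, 0.35²)`. The hinge on the ln scale reproduces the
  characteristic pattern of damage staying near a low baseline (~2–3% of
  leaf area) until about 0.6 insects/young leaf and rising steeply
  beyond it, reaching ~10% at the highest densities. The generating
  process is a modelling choice; only the observed threshold shape is
  constrained by the system being emulated.
* **Focal-leaf damage** = mean damage × exp(η), η ~ N(0, s²), with s
  solved in closed form from the realised sample moments of mean damage
  so that the expected Pearson correlation between mean and focal damage
  equals the configured target (default 0.71). The sample correlation of
  this heavy-tailed product is noisy even at n = 2000, so calibration
  checks average several seeds.
* **Compounds**: 12 step / 11 linear / 12 null (hinge available, default
  0). Per-compound ln-scale response `α + f(x) + ε`, `ε ~ N(0, 0.5²)`;
  intercepts α ~ U(−3, 1) (ln RPA units), linear slopes U(1.5, 4.0) per
  insect/leaf, step jumps U(1.6, 7.2) ln units, change points
  U(0.25, 0.77) insects/leaf. Ranges bracket the magnitudes a field
  experiment of this kind reports; σ = 0.5 ln units is the "data-scale"
  noise used throughout the recovery checks.
* The **peak-table generator** inverts preprocessing exactly:
  `area = (exp(ln value) + blank RPA) · IS`, one field-blank row, one IS
  column, so `preprocess` recovers the input matrix for compounds not
  touched by the floor or prevalence rules (round-trip identity, tested).
* The **LC-MS-like block** (`simulate_concentrations`) applies the same
  shape machinery directly on the concentration scale (responses to
  ln mean damage, default 4 negative-linear + 8 null compounds, mg/g-like
  baselines 40–160, σ = 3), because the downstream univariate fits for
  that block run on concentrations, and a linear truth on the ln scale
  would not be linear there.

What the generator does **not** emulate: chromatographic peak shapes,
retention behaviour, spectra, detection-limit censoring correlated with
abundance, between-compound correlation beyond the shared predictor, and
real leaf morphology (leaves are ellipses with disk-shaped lesions).
Passing tests therefore demonstrate correctness of the computations and
calibration of the inference under Gaussian ln-scale noise — not
robustness to every artefact of real chromatography.

## Preprocessing conventions

Fixed order: RPA → blank subtraction → prevalence filter → ln →
outlier flagging → autoscale; each stage logs row/column counts.

* "Detected" means strictly above that sample's `100/IS` floor; a
  corrected RPA ≤ 0 (including exactly 0) is a non-detection and is
  floored. Compounds detected in ≤ 5 samples are dropped.
* The floor uses the per-sample IS area (not a batch constant).
* Sample standard deviations use n − 1 throughout.
* Multiple blank rows, if supplied, are averaged before subtraction.
* Constant (zero-variance) compounds cannot be autoscaled and are
  excluded from the ordination input with a log entry; they remain in
  the ln matrix and are still shape-classified (a constant compound is
  trivially "null").
* **Outlier flagging** follows the nearest-neighbour-distance idea:
  standardise columns, compute each sample's Euclidean nearest-neighbour
  distance, fit an exponential (MLE) to the gaps between consecutive
  sorted distances in the upper half, and flag every sample beyond the
  first gap exceeding the fitted tail quantile. The quantile is
  Bonferroni-adjusted for the number of gaps examined, so on clean data
  the chance of flagging anything stays near α (measured false-flag
  fraction ~0.01 at α = 0.05, n = 50 — well under the 2α design bound).
  Flagging and removal are separate steps so removal is auditable; the
  outlier is removed from the volatile block only.

## Ordination and biomarkers

With one predictor the constrained space is one-dimensional, so the
"first axis" is exact: the centred fitted matrix is rank 1,
`Ŷ_c = x̃ b'`, site scores are `x̃·‖b‖` (oriented so they correlate
positively with x) and loadings are `b/‖b‖`. R², F and df satisfy
`F = (R²/q)/((1−R²)/(n−q−1))` identically; with 18 samples the test
reports F(1, 16).

* Permutation scheme: unrestricted permutation of x, B = 999 by default,
  `p = (1 + #{F_perm ≥ F_obs})/(1 + B)`. Samples are put in a canonical
  order (sorted by x) before drawing permutations, which makes the
  realised p invariant to relabelling samples jointly in Y and x (up to
  ties in x).
* Axis correlations use the two-sided t test on n − 2 df. No multiple
  testing correction by default — the biomarker lists this style of
  analysis reports are consistent with uncorrected α = 0.05 —
  Benjamini-Hochberg is available by flag.
* Ordering is by |r| descending; ties break lexicographically by
  compound id.

## Dose-response competition

* **Hinge form**: `y = α + β·(x − e)₊` — flat below the change point,
  linear above. This is the natural threshold-linear complement to the
  step model in change-point regression.
* **Candidate grid**: midpoints between consecutive distinct x values
  with at least `min_seg = 2` observations per segment; the estimate is
  reported as the winning midpoint. RSS ties resolve to the smallest e.
* **AIC**: `n·ln(RSS/n) + 2k`, with the change point counted as a
  parameter and the error variance counted for every model (k = 2, 3, 4,
  4 for null/linear/step/hinge). Counting conventions differ between
  packages; comparable penalties across forms is the criterion used
  here. RSS = 0 maps to an AIC of −∞ with a warning; competition stays
  deterministic through the tie rules (fewer parameters first, then
  null > linear > step > hinge).
* **Bootstrap**: nonparametric case resampling (default B = 1000),
  percentile intervals for e and Δ (step) or β (hinge). Resamples are
  conditioned on identifiability — at least `min_seg` points on each
  side of the fitted change point — because a resample entirely on one
  side carries no information about the threshold. Because the data
  identify a change point only up to the gap between adjacent observed
  x values, each interval end is widened to the observed value bounding
  the gap that contains it. Without the widening the percentile interval
  covers a true change point ~87% of the time at the nominal 95% level
  (n = 100); with it, measured coverage is ~98% (n = 100, jump 2,
  σ = 0.8, 300 replicates).
* **Threshold significance**: a winning step or hinge is kept only when
  the widened e-interval lies strictly inside (min x, max x) and the
  effect interval excludes 0; otherwise it is demoted to the next-best
  AIC (cascading, logged). On pure noise at n = 19 this keeps the rate
  of non-null selections with ΔAIC > 2 at or below ~10%.
* The scalar-response variant additionally reports the OLS slope t-test
  p-value when the linear model wins, for total-polyphenol-style
  univariate analyses.

## Damage stage

The pixel classifier is deliberately minimal: per-class colour mean and
covariance estimated from labelled pixels, nearest class under
Mahalanobis distance, optional Gaussian pre-smoothing. A trainable
feature-bank segmenter would outperform it on real scans; the
deliverables of this module are the damage metric and its evaluation,
not segmentation research. On the synthetic fixtures (colour noise sd 5
of 255) it recovers generated damage fractions within a few tenths of a
percentage point and agrees with truth masks at kappa > 0.999. Cohen's
kappa is computed from the 3-class confusion matrix; if both masks are a
single identical class (p_e = 1) kappa is defined as 1 and logged.
Manually excluded regions (petioles, shadows) are represented by the
background class, which never enters the damage ratio.

## Pipeline conventions

* Volatile block analysed against density, ln mean damage and ln focal
  damage; non-volatile block and total polyphenols against density and
  ln mean damage. Damage predictors are always ln-transformed; density
  is not.
* The dose-response table covers every retained compound with a
  biomarker flag (rather than only significant biomarkers), which makes
  noiseless full recovery testable; presentation tables
  (`make_biomarker_table`) show biomarkers only, with dashes for
  inapplicable parameters.
* Excluded pots (e.g. a pot with necrosis unrelated to the treatment)
  are an input-data decision, given as a config list, not an automated
  rule.
* Everything is driven by one integer seed; the same seed yields
  byte-identical report tables (hash-tested).

## Problem sizes in the test suite

Monte-Carlo checks run at sizes chosen to keep the suite fast while
leaving comfortable statistical margins: 100 random instances for the
oracle-equivalence checks; 200 replicates for change-point recovery at
the 19-pot design; 500 replicates (B = 199) for permutation and
false-selection calibration; 300 replicates (bootstrap B = 200) for CI
coverage; 12–20 replicates per shape for selection consistency at
n = 200, σ = 0.1. The full suite runs in well under five minutes on one
CPU.

## Known limitations

* The bootstrap CI for the change point is slightly conservative after
  gap-widening (~98% at nominal 95% in the measured settings).
* The exponential-tail outlier test is calibrated for "flag rarely on
  clean data", not for power against subtle outliers; its leader-style
  compression for very large n is not implemented (n is tens of samples
  here).
* Step/hinge change points are only identified up to the candidate
  grid; with 19 design points the grid resolution near the threshold is
  ~0.05–0.15 insects/young leaf.
* The competition can mislabel shapes that are nearly indistinguishable
  at the design size (e.g. a shallow hinge vs a line); selection
  consistency ≥ 90% per shape was measured at n = 200, σ = 0.1, not at
  n = 19.
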