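# Methods

## Model

The package models a binary discharge diagnosis — incarcerated inguinal
hernia without necrosis (majority class, the cohort's "positive"
label) vs intestinal necrosis (minority, "negative") — from up to 51
numeric clinical features: age (`f0`), a 20-analyte complete blood
count (`f1`–`f20`) and a 30-analyte liver/kidney chemistry panel
(`f21`–`f50`). Three designs reflect which examinations a patient
took: M1 (blood panel), M2 (liver/kidney panel), M3 (both). Age is
offered to all three designs by default; because the source material
never states whether age joined the liver/kidney design, this is a
config switch (`include_age_in`) rather than a hard-coded choice.

### Cohort filtering

Rows are kept by a per-class missing-rate rule: majority rows must be
complete (threshold ≤ 0, configurable), minority rows must have
*strictly less than* 40% of the active design's features missing. The
strict inequality follows the rule's wording ("less than 40%"); the
boundary is unit-tested. The denominator is the feature set of the
active design, not all 51 columns — filtering a blood-panel design
against liver-panel columns would discard every patient who only took
the blood test, which is precisely the population the design exists
for.

### RIN-3M imputation

For each feature with at least one observed value, the mode `m`, mean
`n` and median `p` are computed; a missing cell receives
`(max(m,n,p) − min(m,n,p))·rv + min(m,n,p)` with `rv ~ U[0,1)` drawn
independently per cell. Properties relied on downstream: every imputed
value lies in the half-open envelope `[min, max)` (closed when the
envelope is degenerate), and when `m = n = p` the method *is* mean
imputation, exactly.

Numerical choices:

* **Mode of continuous data.** Lab values are recorded at finite
  precision, so the mode is taken over values rounded to the catalog's
  recorded decimal places (default 2; age 0). Multimodal ties resolve
  deterministically: closest to the median, then the smaller value.
  Continuous analytes genuinely have multiple modes at any finite
  precision; a documented tie rule is what makes the statistic
  reproducible.
* **`rv` endpoints.** "A random number between 0 and 1" is taken as
  `[0, 1)`, matching the standard generator convention.
* **Fitting scope.** Statistics are fitted label-blind on the training
  split only and applied to both splits (a `fit-on: all` switch exists
  for replaying pre-split fits). Fitting on all rows would leak test
  information into training-time imputation.
* **Traversal order.** Cells are imputed in row-major, catalog-column
  order from one seeded generator, so a single seed reproduces the
  imputation bit for bit.

### Sub-balanced voting ensemble

After a stratified hold-out (default 20%; per-class training count
`round_half_up((1−f)·N)` — half-up rounding is the only rule consistent
with all published per-class counts, e.g. 121 → 97/24 and 163 →
130/33), the majority training rows are shuffled and partitioned:

* `k = ⌊N_maj / N_min⌋` subsets,
* subset size `⌊N_maj / k⌋` (each "almost equal" to the minority
  count; bounded by `N_min ≤ size < 2·N_min`),
* the `< k` leftover rows are appended to the majority *test* set
  rather than discarded.

This floor rule reproduces the published partition tables exactly for
the blood-routine design (1906 majority training rows vs 97 minority →
19 × 100 + 6 leftover, giving the printed 483 majority test rows) and
the combined design (654 vs 130 → 5 × 130 + 4 → 168). The published
liver/kidney row (149 × 11 with 135 minority) is inconsistent with any
rule fitting the other two rows (`⌊1643/135⌋ = 12`, and 149 > 135); it
is recorded as an anomaly and not special-cased.

One base learner per subset is fitted on `S_maj_i ∪ S_min`. Defaults
mirror the study settings: random forest with 200 trees, Gini
impurity, `min_samples_split=2`, `min_samples_leaf=1`, `sqrt` features
per split (the historical "auto" for classifiers); SVM with C = 1 and
RBF `gamma="scale"`; logistic regression with tol 1e-4, C = 1,
`max_iter=100`. Features are z-scored (fitted on training rows) for
the scale-sensitive SVM/LR learners, not for forests; this is
switchable.

Fusion: the ensemble score is the mean of the sub-models' minority
(necrosis) probabilities; for hard majority-vote fusion the
AUC-compatible score is the fraction of minority votes. Exact ties —
mean score at the 0.5 threshold, or an even vote split — classify as
necrosis, because a missed necrosis is the costly clinical error. The
threshold is configurable.

### Feature selection

Gini (impurity-reduction) importance is recorded by one forest per
stratified CV fold (default 5) on that fold's training portion;
the per-fold vectors each sum to 1 and their mean is the score.
Ranking ties break by catalog order for determinism.

`FI` = (top-15 of M3 ∩ top-10 of M1) ∪ (top-15 of M3 ∩ top-10 of M2),
ordered by M3 rank. Applied to the published rankings of the original
hospital cohort (recorded verbatim in `necrotriage.reference`), the
intersections have sizes 5 and 7 and the union 12; the published text
states 11, and this discrepancy — together with the printed ranking's
"Mean hemoglobin", which matches no blood-panel entry exactly and is
resolved to "Mean corpuscular hemoglobin" — is carried in the
provenance record rather than silently repaired.

`FC_k` is a best-prefix sweep: for k = 1…15 the *full* pipeline
(partition, ensemble, CV) is evaluated on the top-k prefix of the
ranking and the metric-maximizing k wins, ties to the smaller k. A
prefix sweep, not a 2^15 subset search, because the quantity being
optimized is "number of top-ranked features"; an exhaustive mode
(≤ 12 candidates) exists and is used as a brute-force cross-check in
the tests.

### Evaluation

`ACC = (TP+TN)/total`, `SN = TP/(TP+FN)`, `SP = TN/(TN+FP)` with
positive = majority (hernia-only). The orientation is printed in every
report because sensitivity/specificity silently swap if the positive
class flips. Undefined ratios (an absent class) are flagged, never
reported as 0. AUC uses the rank / Mann–Whitney formulation with half
credit for ties, oriented as separation of the minority class by
ascending score; it equals the concordant-pair fraction, which the
tests verify against a brute-force oracle. Cross-validation re-runs
the entire pipeline (imputation fitting included) inside each fold.

## Synthetic cohorts

The generator emulates the statistical shape of the (non-public)
hospital cohort, not its marginals:

* class counts 3,807 / 170 by default;
* within-panel equicorrelated Gaussians (ρ = 0.2), baseline mean 50,
  SD 10, rounded to catalog precision; age is an integer,
  class-independent covariate;
* minority-class mean shifts on five informative features: a
  C-reactive-protein-like marker at +2.0 SD and four secondary markers
  (troponin I, direct bilirubin, basophil ratio, mean corpuscular
  volume — mirroring the second-gradient markers reported for the real
  cohort) at +0.8 SD;
* missingness in two layers: per-cell MCAR at class-specific rates
  (defaults: minority 0.25, majority 0.0 — majority rows complete,
  matching the filtering rule's premise) and optional whole-panel
  absence per patient (default probability 0; block absence is
  exercised explicitly in tests). Age is never masked: it is
  demographic, not an examination result.

What passing tests on these cohorts do **not** show about real data:
Gaussian marginals carry none of the skew, detection limits or unit
heterogeneity of real analytes; MCAR cell missingness is more benign
than clinically driven missingness; and effect sizes are planted, not
estimated. The published performance of the original cohort (ACC
86.43%, SN 84.34%, SP 96.89%, AUC 0.91 for the selected feature set)
is therefore *not* a reproduction target — only the cohort
bookkeeping, the method's invariants and its behavior under controlled
signal are.

### Class-dependent missingness is itself a signal

One property worth stating loudly: with class-dependent missingness
(sparse minority rows, complete majority rows), *any* single-value
imputation — RIN-3M included — leaves a detectable signature: imputed
cells concentrate inside the narrow mode/mean/median envelope, and a
forest learns "many near-center values ⇒ minority" even when the
classes share one value distribution. On zero-effect cohorts *with*
injected class-dependent missingness the pipeline therefore reaches
AUC well above chance from the missingness pattern alone. The null
calibration is consequently defined on complete null cohorts (zero
effect sizes, no missingness injection), where the two classes are
genuinely drawn from one distribution; mean hold-out AUC sits in
[0.45, 0.55] there. On real data this effect would partially inflate
apparent performance whenever missingness correlates with outcome —
a caveat inherited by any study with class-dependent missingness and
class-blind imputation.

## Problem sizes used by the test and acceptance suites

The repeated-seed suites (signal recovery over 100 seeds, null
calibration over 50) run on a quarter-scale cohort — 952 majority / 42
minority rows, preserving the 22.4 : 1 imbalance, the missingness
rates and the effect sizes — chosen as the largest size whose
hundredfold repetition stays comfortably inside a routine CI run; the
partition rule then yields k = 22 sub-models per ensemble, the same
order as the full-size cohort's k. The acceptance script runs the same
conditions over 20 signal and 10 null seeds. Arithmetic checks
(splits, partitions, FI sets) run at the published sizes exactly,
since they involve no model fitting.

## Known limitations

* The minority-class tie rule and the 0.5 threshold encode an asymmetric
  cost judgment; calibrating the threshold on a validation split would
  be the next step for deployment-grade use.
* RIN-3M ignores between-feature correlation; imputed cells are
  conditionally independent given the fitted statistics.
* Importance-based selection inherits impurity bias toward
  high-cardinality features; all features here are continuous, which
  limits but does not remove the bias.
* The M2 partition-row anomaly means published M2 bookkeeping cannot be
  reproduced by any single consistent rule; the package applies the
  floor rule uniformly.
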