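# Methods note

This note records what the package computes, the assumptions behind each
step, the tunable parameters with their defaults, what the synthetic
generators do and do not emulate, and the numerical and design choices made
where the procedure admits more than one reasonable reading.

## 1. Data model

Expression data are log2-scale gene × sample matrices (`ExpressionMatrix`),
tagged with species and cohort and with flags recording whether the matrix
has been per-gene standardized and whether duplicate probes have been
collapsed. Clinical data (`ClinicalTable`) require non-negative follow-up
times (`os_months`) and binary event indicators (`os_event`); optional
columns (stage, tumor size, AFP, subtype labels, `RS_score` in [0, 100]) are
validated when present and missing values are preserved, never silently
imputed (mean imputation exists only behind an explicit flag in
`read_expression`). Ortholog maps are unordered pairs of (mouse symbol,
human symbol); regulator networks are signed edges (regulator, target,
±1) with duplicate and invalid-sign detection.

`summarize_cohort` reproduces baseline-table arithmetic: counts per level,
percentages rounded half-up (⌊x + 0.5⌋), denominators including missing
values, and `NA` reported as its own level.

## 2. Signature derivation

Given an **unstandardized** log2 matrix and two-class labels
(perturbed / control), each gene is tested with the pooled-variance
two-sample t-test. A gene is selected when

- p < `p` (default 0.005, two-sided), and
- |mean(perturbed) − mean(control)| ≥ log2(`fold`) (default fold = 1.5).

Assumptions: approximately Gaussian per-gene log2 noise with equal class
variances. Genes with zero within-class variance get t = ±∞ (p = 0) when the
means differ and t = 0 (p = 1) when they agree. Selected genes are ordered
by ascending p. The t-test is vectorized in-house (`_t_vectorized`) because
the honest cross-validation loop re-runs it genome-wide per fold; it is
tested gene-by-gene against `scipy.stats.ttest_ind`, including a
property-based (hypothesis) comparison.

The estimator form is `SignatureSelector` (a scikit-learn transformer:
`fit(X, y)` stores `support_`, `selected_idx_`, `t_`, `p_values_`, `diff_`;
`transform` subsets columns), so the selector composes in sklearn pipelines.
`derive_signature` is the thin wrapper producing a `GeneSignature` with
per-gene t, difference, p, and direction.

## 3. Cross-species transfer

1. **Duplicate collapse**: among probes mapping to one symbol, keep the one
   with maximal variance (first listed on ties).
2. **Ortholog restriction**: mouse and human matrices are restricted to
   mapped pairs; many-to-many mappings are resolved by keeping, per human
   symbol, the mouse gene of maximal variance (and symmetrically), yielding
   a 1:1 map. Rows are re-indexed to human symbols.
3. **Per-dataset standardization**: every gene is centered and scaled to
   mean 0, SD 1 (ddof = 1) within each dataset separately, removing
   platform/species location-scale differences. Constant genes become
   all-zero rows and are flagged. Standardizing twice is rejected.
4. **Pooling**: standardized matrices are joined on common genes; sample
   provenance is kept in `sample_meta`. Note that a pooled matrix's rows no
   longer have unit SD (the within-dataset centering removes between-dataset
   variance), which is expected and accounted for.
5. **Anchored clustering** (`CorrelationCluster` / `hier_cluster`):
   hierarchical clustering with distance 1 − Pearson correlation, average
   linkage, cut at k = 2, restricted to signature genes. The cluster
   containing the majority of perturbed mouse samples is labeled
   `ASS_present`; a 50/50 split of the anchors is an error, not a silent
   choice. Leaf order is made deterministic (lower-height subtree first).

## 4. BCCP — Bayesian compound covariate predictor

For sample i, the compound covariate is c_i = Σ_j t_j x_ij over signature
genes, t_j the training t-statistic. Training (`BCCPClassifier.fit`)
estimates class means m₁ (present), m₀ (absent) of c and the pooled
within-class SD s; the posterior is

    P(present | c) = π₁ φ(c; m₁, s) / (π₁ φ(c; m₁, s) + π₀ φ(c; m₀, s))

with default equal priors π₁ = π₀ = ½. The posterior is evaluated in
log-space (log-density difference through a logistic), so it is finite and
correct even for |c| far outside the training range, where naive density
ratios underflow to 0/0. A sample is called `ASS_present` iff
P(present | c) > 0.5 strictly; exact ties go to `ASS_absent`. Degenerate
training (s = 0) is an error. Missing signature genes in a test matrix are
dropped pairwise from c; fewer than a minimum overlap (default 10) is an
error rather than a silent near-empty covariate.

**Honest LOOCV** (`bccp.loocv`): for each held-out sample the signature is
re-selected from scratch on the remaining samples (log2 scale), the
training fold is standardized with its own means/SDs, those same means/SDs
are applied to the held-out sample, and the classifier is refit. Nothing
from the held-out sample touches selection or scaling. If a fold selects no
genes, the posterior falls back to the prior (→ `ASS_absent` under equal
priors) and the fold is logged. Reported: misclassification rate,
sensitivity, specificity, per-sample calls.

## 5. Survival analysis

- **Kaplan–Meier**: lifelines `KaplanMeierFitter`, exposed as a `KMEstimate`
  with timeline, survival, at-risk/event counts and Greenwood variance.
- **Log-rank** (two groups): implemented directly over the risk-set
  representation, observed-minus-expected with the hypergeometric variance
  including the (n − d)/(n − 1) tie factor; χ² on 1 df. Cross-checked in
  tests against lifelines' `logrank_test` and against the Cox score test.
- **Cox PH**: lifelines `CoxPHFitter` with Efron tie handling. A `ties`
  argument exists for interface clarity but any value other than `"efron"`
  raises, because lifelines implements only Efron; silently ignoring the
  argument would misreport the method. Rows with missing covariates are
  listwise-deleted and the number dropped is reported. Constant covariates
  and zero-event data raise informative errors.
- **Score-test oracle**: `cox_score_chi2` evaluates U²/I at β = 0 for a
  single binary covariate; on untied data this equals the log-rank χ²
  (classical identity), used as an exact cross-check between the two code
  paths.
- **Subgroup analysis**: survival comparisons within clinical strata
  (e.g. stage I/II only); degenerate strata (one group empty, or no events)
  return the KM fits with the test set to None and a warning, rather than a
  fabricated p-value.

Assumptions: non-informative censoring; proportional hazards for the Cox
model. Calibration is verified empirically (type-I error of the log-rank at
the 5% level over 2000 null replicates; 95% CI coverage of the Cox HR at a
true HR of 2 over 500 replicates).

## 6. Concordance and external classification

Agreement between the binary BCCP call and alternative subtype labels is a
cross-tabulation with Pearson's χ² (scipy, **no** continuity correction);
tables with a zero margin are an error. Continuous risk scores
(`RS_score`) are dichotomized at > 50 (strict). `classify_external`
re-derives subtype calls on a new cohort either by correlation-based
nearest centroid (`CorrelationNearestCentroid`) or, when only a signature
with weights is available, by the compound covariate followed by a
two-component (2-means) split of c with the higher-c component mapped to
the class favored by the positive weights — the publication-style pipelines
do not print this mechanism, so the choice is documented here and kept
behind an explicit `method=` argument.

## 7. Shared signature and regulator scoring

`shared_signature` intersects per-cohort differential-expression tables
(default per-cohort thresholds fold = 1.2, p = 0.01 — looser than the
derivation thresholds because the intersection itself is the filter) and
keeps genes whose direction agrees in every cohort, in first-cohort order.

For a regulator R with signed targets, the activation score over a
direction-labeled gene set is

    z = Σ_{targets ∩ set} (edge_sign × direction) / √n_overlap,

with R called activated at z ≥ 2 and inhibited at z ≤ −2 (two-sided normal
≈ 0.05). Overlap enrichment is the hypergeometric tail
P(X ≥ k) = `hypergeom.sf(k − 1, N, K, n)`; regulators with zero overlap are
skipped, not scored at z = 0.

## 8. Synthetic data

**Mouse generator** (`simulate_mouse`, `MouseSimConfig`): `n_backgrounds`
(default 2) genetic backgrounds × (2 siRNA arms + 1 control arm) ×
`n_per_arm` (default 6) replicates. Per-gene baselines are N(8, 1.5²) log2
units, iid N(0, `noise_sd`²) noise (default 0.5), a shared per-background
offset N(0, `batch_sd`²) (default 0.25), and `n_de` (default 150) planted
signature genes, half up / half down, shifted by
`effect_size` × `noise_sd` (default 3 SD) in perturbed samples. Returns the
matrix, labels, and a truth table with directions. What it does **not**
emulate: probe-level artifacts, count-based (negative-binomial) noise,
gene–gene correlation beyond the batch offset, or incomplete knockdown.
Calibration checks that need an exact null set `batch_sd = 0`, because the
pooled t-test is exact only under iid noise — a shared batch offset makes
it conservative by construction; this was fixed before any calibration test
was run.

**Cohort generator** (`simulate_cohort`, `CohortSimConfig`): each of
`n_patients` (default 300) patients draws a latent Bernoulli(`prevalence`)
signature-present class. Expression contains the human orthologs of a
supplied mouse signature (symbols upper-cased — the identity-orthology
convention used throughout the simulations) shifted by `class_shift`
(default 2) × `noise_sd` in the direction of the mouse truth for
class-positive patients, plus `n_genes` background genes. Survival is
exponential with hazard `baseline_hazard` × `hazard_ratio`^class
(defaults 0.02, 2.0); censoring is exponential with the per-class rate
calibrated so the expected censored fraction equals `censoring_rate`
(default 0.3) in each class. Alternative subtype labels (NCIP, HS, SNUR)
agree with the latent class with probability `concordance` (default 0.9);
`RS_score` is uniform on (50, 100] for class-positive and [0, 50]
otherwise. Clinical covariates (stage, tumor size, AFP) are mildly
class-associated. Not emulated: competing risks, non-proportional hazards,
cohort-specific platform effects beyond what standardization removes, and
real subtype biology — the labels exist to exercise the concordance
machinery, not to model it.

Randomness uses `numpy.random.SeedSequence` spawning so each sub-process
(expression, survival, censoring, labels) has an independent substream; all
derived integer seeds are kept below 2³¹.

## 9. Orchestration and reproducibility

`run_pipeline(seed, …)` chains the whole method on synthetic inputs:
simulate mouse → derive signature → honest LOOCV → per cohort
(simulate → ortholog-map → standardize → pool with mouse → anchored
clustering → BCCP train/predict → KM + log-rank → Cox adjusted for stage
and tumor size → stage-I/II subgroup → concordance vs all label systems →
per-cohort DE) → shared signature across cohorts → regulator scoring
against a synthetic signed network whose regulators partition the planted
genes. Cohort i uses seed × 1000 + i. The `crossig` CLI exposes each stage
and `run-all`, writing artifacts and a JSON run manifest per stage.

`scripts/acceptance.py --seed S --out F` recomputes the headline
quantities (baseline-table percentages; max |posterior − 50-digit Bayes
formula| via mpmath; LOOCV sensitivity/specificity and null accuracy;
signature recall/FDR and null selection rate; log-rank type-I rate; Cox
coverage; score/log-rank max discrepancy; pipeline accuracy and success
rates) from the single seed, offline, in about a minute.

## 10. Numerical choices

- Posterior in log-space (logistic of log-density difference): exact at the
  midpoint, no underflow at extreme c.
- SDs use ddof = 1 everywhere; constant rows standardize to zeros with a
  flag rather than NaN.
- p-values from `scipy.stats.t.sf` on |t| × 2; ±∞ t maps to p = 0.
- Strict inequalities at every decision boundary (p < threshold, fold ≥
  log2(fold), posterior > 0.5, RS > 50, |z| ≥ 2) so boundary behaviour is
  defined, tested, and documented rather than platform-dependent.
- Hierarchical clustering uses scipy's condensed-distance path; correlation
  distance on standardized rows is numerically clamped to [0, 2].

## 11. Problem-size defaults

The defaults above (5000 mouse genes / 150 planted / 6 per arm; 300
patients / 2000 background genes / HR 2 / 30% censoring; 2 cohorts) are the
package's own choices, sized so that the full test suite and the
acceptance script run in minutes on one CPU while every statistical
property being claimed (recall, calibration, coverage, end-to-end success)
is testable with meaningful replicate counts.

## 12. Limitations

- Equal-variance Gaussian assumptions in both the gene-level t-test and the
  BCCP class model; no moderated-variance (limma-style) option.
- Cox tie handling is Efron only (see §5).
- No multiple-testing correction in signature derivation — the method is
  defined by fixed p/fold thresholds, and its false-discovery behaviour is
  characterized empirically instead.
- The ortholog resolver's variance heuristic is a convention, not biology;
  real many-to-many homology may warrant curation.
- The synthetic cohorts make the cross-species transfer easier than real
  data (shared noise model, exact orthology); the generators are for
  verifying the machinery with known truth, not for power analysis of real
  studies.
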