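# crossig

Cross-species transfer of a gene-expression signature from a controlled
mouse perturbation experiment to human tumor cohorts, with the downstream
statistics that make such a transfer clinically interpretable: survival
analysis, molecular-subtype concordance, a cross-cohort shared-gene
signature, and upstream-regulator activation scoring.

## The problem

Silencing a gene in mouse liver (here, apolipoprotein B knocked down with
siRNA) changes the expression of many downstream genes. If a subset of human
hepatocellular carcinomas shows the same transcriptional footprint, those
tumors plausibly share the silenced gene's biology — and the footprint
becomes a prognostic biomarker. The analytical chain is:

1. **Signature derivation.** In the two-class mouse experiment (perturbed vs
   control), a gene enters the signature when it passes a pooled-variance
   two-sample *t*-test at *p* < 0.005 **and** a 1.5-fold change filter
   (|difference of log2 class means| ≥ log2 1.5).
2. **Cross-species pooling.** Mouse and human matrices are restricted to 1:1
   orthologs, each gene is independently standardized per dataset to mean 0,
   SD 1, and the matrices are pooled. Unsupervised clustering
   (1 − Pearson correlation, average linkage, cut at k = 2) splits the pooled
   samples; the cluster holding the majority of perturbed mouse samples
   anchors the "signature present" label.
3. **Bayesian compound covariate prediction (BCCP).** Each sample gets a
   compound covariate c = Σⱼ tⱼ xⱼ over signature genes (tⱼ = training
   *t*-statistic). Training fits a two-class equal-variance Gaussian model of
   c (means m₁, m₂, pooled SD s, priors π₁ = π₂ = ½); the posterior

       P(present | c) = π₁ φ(c; m₁, s) / (π₁ φ(c; m₁, s) + π₂ φ(c; m₂, s))

   is dichotomized at 0.5 (strict). Classifier robustness is assessed by
   honest leave-one-out cross-validation with in-fold re-selection of the
   signature.
4. **Consequences.** Kaplan–Meier curves and the two-group log-rank test
   compare survival between calls; Cox proportional hazards (Efron ties)
   adjusts for stage and tumor size; Pearson χ² (no continuity correction)
   tests concordance with alternative subtype labels; a direction-consistent
   intersection of per-cohort differential genes yields the shared
   signature; and a signed regulator→target network gives per-regulator
   activation z = Σ(sign·direction)/√n, called activated at z ≥ 2 and
   inhibited at z ≤ −2.

Because the original cohort data are access-restricted, the package ships a
first-class synthetic-data module that reproduces the statistical structure
of every input — the two-background siRNA design with a planted signature,
and human cohorts with a latent signature-present class, class-dependent
exponential survival with calibrated censoring, correlated clinical
covariates, and noisy alternative subtype labels — so the whole chain is
exercised end-to-end with known ground truth.

## Worked example

```python
from crossig import (MouseSimConfig, simulate_mouse, derive_signature,
                     run_pipeline)

m, labels, truth = simulate_mouse(MouseSimConfig(seed=1))
sig = derive_signature(m, labels, fold=1.5, p=0.005)
print(len(sig))                       # 157 genes (80 up, 77 down; 150 planted)

res = run_pipeline(seed=1, n_cohorts=2)
coh = res["cohorts"][0]
print(coh["accuracy"])                # 1.000  (BCCP call vs latent truth)
print(coh["logrank"]["p"])            # 1.27e-05
print(coh["cox"].hr("call"))          # 1.99   (simulated hazard ratio: 2)
print(len(res["shared_signature"]))   # 150 genes shared across both cohorts
print(res["regnet"].head(1))
#            n_overlap      z  overlap_p      state
# REG_0             38  6.164   7.93e-83  activated
```

The mouse generator plants a 150-gene signature at a 3-SD log2 shift; the
derivation recovers all of it plus a handful of chance genes, the
cross-species BCCP calls reproduce the latent tumor class, the log-rank and
Cox analyses recover the simulated survival difference (true HR = 2), and
every synthetic regulator whose targets sit in the signature scores as
activated.

The same stages are scriptable from a shell:

```bash
crossig --seed 1 --out-dir out run-all            # full chain + all reports
crossig --seed 2 --out-dir out simulate           # data only
crossig --out-dir out derive-signature \
    --expression out/mouse_expression.tsv --labels out/mouse_labels.tsv
```

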