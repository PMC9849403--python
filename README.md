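# apmcluster

Antigen-presenting-machinery (APM) clustering of tumor transcriptomes,
with tumor-purity correction of MHC class I expression.

## The problem

Tumors present peptide antigens to T cells through the MHC class I and
class II pathways, and how strongly a tumor expresses this
antigen-presenting machinery shapes its response to immune checkpoint
blockade (ICB).  Bulk RNA-seq mixes malignant and non-malignant cells,
and MHC class I genes are typically expressed more highly by infiltrating
immune cells than by the tumor itself, so raw bulk expression overstates
tumor-intrinsic antigen presentation.  `apmcluster` implements a complete,
testable pipeline for melanoma-style ICB cohorts:

1. **Purity correction.** Bulk expression of gene *x* in sample *i* is
   modelled as a purity-weighted mixture of malignant (γ) and
   non-malignant (λ) profiles,

       β_xi = γ_xi · p_i + λ_xi · (1 − p_i),   λ_x = N_x · γ_x,

   where the purity *p* comes either from single-cell annotations or from
   an ESTIMATE score via `purity = cos(0.6049872018 + 0.0001467884 ·
   score)`, and the cohort-wide normalization factor

       N_x = Σ_i λ_xi / Σ_i γ_xi

   is estimated from patient-level single-cell pseudobulk.  The mixture is
   then inverted, `γ_xi = β_xi / (p_i + N_x − N_x·p_i)`, for the 17 MHC
   class I pathway genes; class II genes are expressed by immune cells and
   left uncorrected.
2. **Signature selection.** Starting from a fixed 16-gene base model
   (HLA class I/II genes plus the transactivators *NLRC5* and *CIITA*),
   every one of the 2¹⁶ = 65,536 subsets of 16 additional APM features is
   added, samples are clustered (complete linkage, Euclidean distance on
   log2(TPM+1), four clusters), and candidates are ranked by the k-group
   log-rank p-value of the clusters against survival — worst cohort first
   — across the discovery cohorts.  The winning combination joins the
   base model to form the published 23-gene APM signature.
3. **Cluster transfer.** A multinomial logistic regression (saga solver,
   C = 8, ≤ 1500 iterations) on HG7 housekeeping-normalized signature
   expression transfers the C1–C4 labels to new bulk or single-cell
   (pseudobulk) cohorts, evaluated by repeated stratified tenfold
   cross-validated micro-AUC.
4. **Outcome statistics.** Kaplan–Meier curves, k-group log-rank tests,
   multivariate Cox models (clusters coded C1=1 … C4=4), durable clinical
   benefit (DCB/NCB) derivation from RECIST best overall response, exact
   cluster×benefit association tests, paired pre/on-treatment comparisons,
   the cytolytic (CYT) score, and Spearman/BH utilities.

Real ICB cohorts live behind controlled access, so the package ships a
first-class synthetic-cohort generator (`apmcluster.simulate`) that plants
the structure the analysis assumes — compartment expression ratios,
four-group APM structure, cluster-dependent hazards and response — and
carries the ground truth for recovery tests.

## Worked example

```python
import apmcluster as apm

# single-cell cohort -> normalization factors
cells, _ = apm.generate_sc_cohort(seed=0)
profiles = apm.build_pseudobulk_profiles(cells)
factors = apm.compute_normalization_factors(profiles)

# bulk cohort -> purity correction -> four APM clusters
expr, clinical, purity, truth = apm.generate_bulk_cohort(seed=0)
corrected = apm.correct_bulk_expression(expr, purity, factors)
results = apm.APMClusterModel(corrected, clinical=clinical).fit()
print(results.summary().round(3))
lr = results.logrank()
print(f"log-rank chi2 = {lr.statistic:.1f}, df = {lr.df}, p = {lr.p_value:.2e}")
```

prints

```
          n  mean_signature_log2tpm  median_survival
cluster
C1       39                   8.266           35.276
C2       36                   7.267           12.030
C3       34                   5.702           13.093
C4       51                   4.020            4.928
log-rank chi2 = 71.4, df = 3, p = 2.18e-15
```

The estimated normalization factors sit at the planted value (≈ 3; e.g.
B2M 3.035, HLA-A 2.984), the four clusters order by mean signature
expression exactly as the C1–C4 convention demands (C1/C2 high-APM,
C3/C4 low), and survival separates sharply because the generator ties the
hazard to the planted cluster.  `results.benefit_association()` reports
the fraction of durable clinical benefit per cluster (here C1 82.1% down
to C4 25.5%, two-sided exact test p = 5.8e−08) and `results.cox()` the
hazard ratio per cluster step (HR = 1.93).

A `ClusterClassifier` trained on these labels
(`results.train_classifier()`) transfers them to any cohort with the 23
signature genes plus the seven housekeeping genes; `apm.predict_clusters`
accepts bulk matrices or compartment-split single-cell pseudobulk.

The same stages are scriptable through the `apmcluster` CLI
(`simulate`, `pseudobulk`, `normfactors`, `correct`, `select-signature`,
`train-classifier`, `predict-clusters`, `evaluate`).

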