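# Methods

## Purity mixture model

Bulk RNA-seq expression of gene *x* in sample *i* is modelled as a
purity-weighted average of a malignant profile γ and a non-malignant
profile λ:

    β_xi = γ_xi · p_i + λ_xi · (1 − p_i).

Assuming a cohort-level proportionality λ_x = N_x · γ_x, the mixture is
invertible:

    γ_xi = β_xi / (p_i + N_x − N_x · p_i).

The normalization factor N_x = Σ_i λ_xi / Σ_i γ_xi is estimated from
patient-level single-cell pseudobulk (arithmetic mean TPM over a
patient's cells per compartment, always excluding cells annotated
"undefined").  Only MHC class I pathway genes (B2M, HLA-A/B/C/E/F/G,
ERAP1, NLRC5, PSMB1/2/8/9/10, TAP1/2, TAPBP) are corrected; class II
genes are expressed predominantly by immune cells and pass through
unchanged.

Assumptions worth stating: a single cohort-wide N_x per gene (no
per-cell-type factors — infiltrating T cells and stromal cells are
averaged together); λ strictly proportional to γ across samples; purity
measured without error.  Violations bias the corrected values
multiplicatively but leave the downstream log-scale clustering fairly
robust, because the clustering uses relative differences between samples.

Numerical choices:

- Patients contribute to N_x only when they have ≥ 1 cell in *both*
  compartments; dropping them from numerator and denominator
  symmetrically avoids biasing the ratio.
- The mixture denominator is guarded at ε = 1e−9; it can only vanish when
  the purity and the factor are both near zero, which is reported as an
  error rather than clamped.
- Purity from an ESTIMATE score is cos(a + b·score) with
  a = 0.6049872018 rad, b = 0.0001467884 rad per score unit.  Arguments
  outside [0, π/2] are clamped so purity stays in [0, 1], with a logged
  warning; the inverse transform (used by the simulator to emit ESTIMATE
  scores) is (arccos p − a)/b.

## Signature selection

The base model is fixed: 16 genes (six HLA class I, eight HLA class II,
NLRC5, CIITA).  All 2^n subsets of the n = 16 additional candidates
(default: PSME1/2, PSMB8/9/10, B2M, HLA-DRB5/6, HLA-DMA/DMB/DOA/DOB,
ERAP1, TAPBP, TAP1/2) are enumerated in a fixed order (by size, then
lexicographic; the empty set is a legal candidate).  Each augmented gene
set is scored per cohort by:

1. agglomerative clustering of samples on log2(TPM+1) of the genes —
   Euclidean distance, complete linkage, dendrogram cut at k = 4.  These
   defaults match widely used heatmap-clustering conventions and are all
   configurable, as is the per-gene scaling (off by default);
2. a k-group log-rank test of the four clusters against survival.

Candidates are ranked by **max p across cohorts** (the winner must
stratify survival in its *worst* cohort), with ties broken by total p,
then fewer genes, then lexicographic order — a total, reproducible
order.  The aggregation key is pluggable because different reasonable
keys (max, sum, Fisher combination) coexist in practice.

Cluster naming is a fixed convention, applied after every 4-way cut: the
two clusters with higher mean signature expression (mean over samples of
the per-sample mean log2(TPM+1) of the signature genes) form the
high-APM pair, the others the low pair.  Within the high pair, C1 is the
longer-surviving cluster when survival is available (an infinite/never
reached Kaplan–Meier median counts as longest), otherwise C2 is the
higher-expression one; within the low pair C3 > C4 by expression.  Ties
break by cluster size, then by smallest member sample id.

## Cluster transfer

Features are HG7-normalized: per patient, score = log2(mean TPM of ACTB,
GAPDH, UBC, HMBS, TBP, HPRT1, RPL13A + 1); the cohort scalar is the mean
score; features are log2(TPM+1) of the signature genes divided by that
scalar.  "Log average expression" is read as the log of the average
(not the average of logs), with a +1 pseudo-count guarding zeros; both
choices are exposed through the code because neither the base nor the
pseudo-count is canonical.  The division acts on log-scale expression;
dividing linear-scale expression is the documented alternative.

The classifier is an L2-penalized multinomial logistic regression (saga,
C = 8, max_iter = 1500; hitting the iteration cap logs a warning).
Cross-validation is stratified tenfold, repeated (default 50 repeats for
speed, 1000 supported); each repeat pools out-of-fold class
probabilities over all samples into one micro-averaged one-vs-rest AUC.
For single-cell cohorts, class I pathway features come from
malignant-cell pseudobulk, class II features from non-malignant
pseudobulk, and the housekeeping scalar from all-cell pseudobulk.
Models serialize to JSON (genes, coefficients, hyperparameters, seed).

## Outcome statistics

- **Log-rank** is computed in its observed-minus-expected form with the
  multivariate hypergeometric covariance at tied event times, so the
  result carries per-group observed and expected counts (they sum to
  equality by construction); the statistic is the quadratic form over
  k−1 groups, χ² with k−1 df.  It agrees with `lifelines` to 1e−9 in the
  test suite.
- **Kaplan–Meier** and **Cox** fits delegate to `lifelines`; Cox uses
  Efron tie handling.  Cluster labels enter Cox as the continuous coding
  C1=1 … C4=4.
- **DCB/NCB**: progressive disease ⇒ NCB; CR/PR or SD ⇒ DCB; mixed or
  non-evaluable responses (or missing BOR) ⇒ DCB iff the patient stayed
  progression-free for ≥ 6 months (times compared in months after unit
  conversion; days are divided by 30.44).  Unknown follow-up withholds
  the label with a warning.
- **Cluster × benefit association**: the omnibus k×2 exact test
  enumerates all tables with the observed margins and sums the null
  probabilities of tables no more probable than the observed one
  (scipy's Fisher test for 2×2; chi-square fallback with a warning past
  500 subjects).  One-vs-rest 2×2 Fisher p-values per cluster are
  reported alongside, since both readings of a k-cluster association are
  in use.
- **Paired comparisons** use the two-sided Wilcoxon signed-rank test on
  mean log2(TPM+1) gene-group scores; zero differences are dropped
  (classical reduction; Pratt's method available via ``zero_method``),
  exact null for ≤ 25 non-zero pairs, normal approximation beyond;
  all-zero differences are reported as "no change" rather than a p-value.
- **CYT** = log2(mean(GZMA, PRF1) + 1).  **Spearman** correlations are
  BH-adjusted across groups; p-values elsewhere are unadjusted.

## Synthetic cohorts

The generators emulate the *statistical* structure the analysis assumes,
not scRNA-seq chemistry: no dropout, no UMI counting, no cell-type
hierarchy below malignant / non-malignant / undefined.  Passing tests
therefore demonstrate correctness of the estimators and the pipeline
logic under the model's own assumptions, not robustness to real-data
artefacts.

- Expression noise is multiplicative log-normal (mean-preserving,
  log-scale SD = "dispersion"), matching the heavy right tail of TPM
  data.  The single-cell default dispersion is 0.3, chosen so that
  pseudobulk estimation at the reference cohort size (20 patients × 200
  cells) recovers planted normalization factors within a few percent —
  the regime the correction method assumes; at dispersion 0 every
  generator identity is exact and the mixture inverts to machine
  precision.
- Bulk cohorts default to four equiprobable clusters with multiplicative
  APM shifts (6, 3, 1, 0.3) on the signature genes, purities uniform on
  (0.2, 0.8), planted N_x = 3 on the class I correction genes, exponential
  survival with hazards (0.02, 0.05, 0.08, 0.2) per month under
  administrative censoring at 36 months, and cluster-specific RECIST
  response probabilities (progressive disease from 10% in cluster 1 to
  70% in cluster 4).  Effect sizes are synthetic choices for clear
  separability — no published between-cluster effect magnitudes exist —
  and are documented as such, not estimated.
- The selection scenario plants one-vs-rest informative genes: candidate
  *j* is elevated (default 16-fold) only in cluster *j*, so each
  informative gene is individually necessary to resolve the clusters and
  the survival separation (hazards 0.01, 0.05, 0.15, 0.5 per month)
  degrades whenever one is dropped.  Base genes carry no signal; the
  remaining candidates are pure noise.
- ESTIMATE scores for synthetic bulk samples are produced by inverting
  the cosine purity transform, so the score→purity→correction path is
  testable end to end.
- All draws flow from one `numpy.random.default_rng(seed)` per generator
  call; identical parameters and seed give bit-identical cohorts.

## Problem sizes

The test suite and `scripts/acceptance.py` use cohorts of 120–200 bulk
samples, 20 patients × 200 cells single-cell, the 8-candidate /
3-informative selection search (256 subsets × 2 cohorts × 20 seeds),
tenfold cross-validation with 5–10 repeats, and 20 replicates of
n = 2000 for Cox calibration.  These sizes put every Monte-Carlo check
well inside its tolerance while keeping a full run around two minutes on
one CPU; the cross-validation repeat count (full scale: 1000) and the
16-candidate powerset (65,536 subsets, enumerated but not survival-scored
in the tests) scale up by configuration only.

## Known limitations

- A single cohort-wide N_x averages over non-malignant cell types; tumors
  whose immune composition differs sharply from the reference single-cell
  cohort are corrected with the wrong factor.
- Housekeeping (HG7) normalization assumes stable housekeeping expression
  across cohorts and disease states.
- The powerset search is exhaustive and guarded at 20 candidates; larger
  candidate pools need a staged search.
- The exact k×2 association test enumerates tables and is intended for
  small cohorts (hundreds of subjects); beyond that it falls back to the
  chi-square approximation.
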