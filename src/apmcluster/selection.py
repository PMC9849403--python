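"""Powerset forward selection of the APM gene signature.

Every subset of the additional candidate genes is added to the fixed base
model; each augmented gene set is scored by cutting a complete-linkage
hierarchical clustering of the samples (Euclidean distance on log2(TPM+1))
into four clusters and testing how well those clusters separate survival
with a k-group log-rank test, independently in each discovery cohort.
Candidates are ranked by their worst-cohort (maximum) p-value so the winner
must stratify survival in every cohort, and the top combination joins the
base model to form the final signature.

Cluster labels follow a fixed convention: the two clusters with higher mean
signature expression are the "high-APM" pair and become C1/C2, the other
two C3/C4.  Within the high pair C1 is the longer-surviving cluster when
survival is available (otherwise C2 is the higher-expression one); within
the low pair C3 has higher expression than C4.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .io import ClinicalTable, ExpressionMatrix, GeneSignature, ValidationError
from .stats import km_curves, logrank_test

logger = logging.getLogger("apmcluster")

MAX_CANDIDATES = 20  # 2^20 subsets is already a million; guard explosion


@dataclass
class ClusterAssignment:
    """Sample → cluster mapping plus the linkage record that produced it."""

    labels: pd.Series                 # sample id -> label (int or C1..C4)
    linkage: np.ndarray = field(repr=False, default=None)
    k: int = 4

    @property
    def cluster_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def relabelled(self, mapping: dict) -> "ClusterAssignment":
        return ClusterAssignment(self.labels.map(mapping), self.linkage,
                                 self.k)


@dataclass
class CandidateEvaluation:
    """One powerset element scored across the discovery cohorts."""

    subset: tuple[str, ...]
    p_values: tuple[float, ...]       # one per cohort, in cohort order
    valid: bool = True

    @property
    def max_p(self) -> float:
        return max(self.p_values)

    @property
    def sum_p(self) -> float:
        return sum(self.p_values)

    def rank_key(self) -> tuple:
        """Total order: worst-cohort p, then total p, then parsimony."""
        return (self.max_p, self.sum_p, len(self.subset),
                tuple(sorted(self.subset)))


def enumerate_candidates(additional: Sequence[str]) -> list[tuple[str, ...]]:
    """All 2^n subsets of the additional features, empty set included.

    Deterministic order: by subset size, then lexicographically.  Guarded
    at 20 candidates; beyond that a staged search is required.
    """
    genes = list(additional)
    if len(set(genes)) != len(genes):
        raise ValidationError("duplicate candidate genes")
    if len(genes) > MAX_CANDIDATES:
        raise ValidationError(
            f"{len(genes)} candidates would enumerate 2^{len(genes)} "
            "subsets; stage the search instead")
    subsets: list[tuple[str, ...]] = []
    for size in range(len(genes) + 1):
        subsets.extend(sorted(itertools.combinations(sorted(genes), size)))
    return subsets


def hcluster(expr: ExpressionMatrix, genes: Sequence[str], k: int = 4,
             transform: str = "log2p1", distance: str = "euclidean",
             linkage: str = "complete",
             missing: str = "error") -> ClusterAssignment:
    """Agglomerative clustering of samples on the listed genes.

    Samples are clustered on log2(TPM+1) of ``genes`` with the given
    distance and linkage, and the dendrogram is cut into exactly ``k``
    groups.  The partition depends only on the data, not on sample order;
    raw group numbers are arbitrary until :func:`label_clusters` applies
    the C1–C4 convention.
    """
    sub = expr.subset_genes(list(genes), missing=missing)
    if transform == "log2p1":
        mat = np.log2(sub.values.to_numpy(dtype=float).T + 1.0)
    elif transform == "none":
        mat = sub.values.to_numpy(dtype=float).T
    else:
        raise ValidationError(f"unknown transform {transform!r}")
    n = mat.shape[0]
    if k > n:
        raise ValidationError(f"cannot cut {n} samples into {k} clusters")
    if np.allclose(mat, mat[0]):
        raise ValidationError("constant expression matrix; no separation")
    dist = ssd.pdist(mat, metric=distance)
    Z = sch.linkage(dist, method=linkage)
    raw = sch.fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(raw, index=sub.sample_ids, name="cluster")
    if labels.nunique() != k:
        raise ValidationError(
            f"dendrogram cut produced {labels.nunique()} clusters, not {k}")
    return ClusterAssignment(labels=labels, linkage=Z, k=k)


def label_clusters(assignment: ClusterAssignment, expr: ExpressionMatrix,
                   signature: Sequence[str],
                   survival: ClinicalTable | None = None
                   ) -> ClusterAssignment:
    """Apply the deterministic C1–C4 naming convention to a 4-way partition.

    Clusters are scored by the mean over samples of the mean log2(TPM+1)
    signature expression.  The two clusters above the median score form the
    high-APM pair (C1, C2) and the rest the low pair (C3, C4).  Within the
    high pair, C1 is the cluster with longer median survival when survival
    data are supplied (C2 the shorter); without survival, C2 is the
    higher-expression cluster.  Within the low pair C3 > C4 by expression.
    Ties are broken by cluster size, then by smallest sample id.
    """
    labels = assignment.labels
    clusters = sorted(labels.unique())
    if len(clusters) != 4:
        raise ValidationError("C1-C4 labeling requires exactly 4 clusters")
    sig = expr.subset_genes(list(signature), missing="drop")
    per_sample = np.log2(sig.values + 1.0).mean(axis=0)

    def tie_key(c):
        members = labels.index[labels == c]
        return (-len(members), min(members))

    score = {c: float(per_sample[labels.index[labels == c]].mean())
             for c in clusters}
    ordered = sorted(clusters, key=lambda c: (-score[c],) + tie_key(c))
    high_pair, low_pair = ordered[:2], ordered[2:]

    if survival is not None:
        med = {}
        joint = labels[labels.index.intersection(survival.sample_ids)]
        curves = km_curves(survival.time.loc[joint.index],
                           survival.event.loc[joint.index], joint)
        for c in high_pair:
            med[c] = curves[c]["median"] if c in curves else np.nan
        # longer median survival -> C1 (NaN median = never reached = longest)
        def surv_key(c):
            m = med[c]
            return (-np.inf if np.isnan(m) else -m,) + tie_key(c)
        high_pair = sorted(high_pair, key=surv_key)
        c1, c2 = high_pair[0], high_pair[1]
    else:
        # C2 is the highest-expression cluster
        c2, c1 = high_pair[0], high_pair[1]
    c3, c4 = low_pair[0], low_pair[1]
    mapping = {c1: "C1", c2: "C2", c3: "C3", c4: "C4"}
    logger.debug("cluster labeling: %s (scores %s)", mapping, score)
    return assignment.relabelled(mapping)


def evaluate_candidate(subset: Sequence[str], base_genes: Sequence[str],
                       cohorts: Sequence[tuple[ExpressionMatrix,
                                               ClinicalTable]],
                       k: int = 4, **cluster_kw) -> CandidateEvaluation:
    """Score base ∪ subset by clustering + log-rank in every cohort."""
    genes = list(base_genes) + [g for g in subset if g not in base_genes]
    ps = []
    valid = True
    for expr, clinical in cohorts:
        if clinical.event.sum() == 0:
            valid = False
            ps.append(1.0)
            continue
        assignment = hcluster(expr, genes, k=k, **cluster_kw)
        joint = assignment.labels.loc[clinical.sample_ids]
        res = logrank_test(clinical.time, clinical.event, joint)
        ps.append(res.p_value)
    return CandidateEvaluation(subset=tuple(subset), p_values=tuple(ps),
                               valid=valid)


def rank_candidates(evaluations: Iterable[CandidateEvaluation]
                    ) -> list[CandidateEvaluation]:
    """Total deterministic order over valid evaluations (best first)."""
    valid = [e for e in evaluations if e.valid]
    if not valid:
        raise ValidationError("no valid candidate evaluations")
    return sorted(valid, key=CandidateEvaluation.rank_key)


def rank_and_select(evaluations: Iterable[CandidateEvaluation],
                    base_genes: Sequence[str],
                    additional: Sequence[str]) -> GeneSignature:
    """Merge the top-ranked combination into the base model."""
    ranked = rank_candidates(evaluations)
    winner = ranked[0]
    return GeneSignature(base_genes=tuple(base_genes),
                         additional_candidates=tuple(additional),
                         selected_additional=winner.subset)


def select_signature(base_genes: Sequence[str], additional: Sequence[str],
                     cohorts: Sequence[tuple[ExpressionMatrix,
                                             ClinicalTable]],
                     k: int = 4, **cluster_kw
                     ) -> tuple[GeneSignature, list[CandidateEvaluation]]:
    """Full powerset search: enumerate, evaluate, rank, select.

    Returns the winning signature and the ranked evaluations.  Warns when a
    cohort matrix is not purity-corrected, since class I genes are expected
    on the corrected scale.
    """
    for expr, _ in cohorts:
        if expr.unit_tag == "TPM":
            logger.warning("cohort matrix is raw TPM, not corrected-TPM; "
                           "MHC-I genes are expected purity-corrected")
    subsets = enumerate_candidates(additional)
    evaluations = [evaluate_candidate(s, base_genes, cohorts, k=k,
                                      **cluster_kw) for s in subsets]
    ranked = rank_candidates(evaluations)
    signature = rank_and_select(ranked, base_genes, additional)
    return signature, ranked
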