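"""Statsmodels-style front end: APMClusterModel / APMClusterResults.

``APMClusterModel`` bundles a (preferably purity-corrected) expression
matrix, a gene signature and an optional clinical table; ``fit()`` runs the
four-cluster hierarchical clustering, applies the C1–C4 naming convention
and returns an ``APMClusterResults`` carrying the assignment, per-cluster
summaries, survival tests and benefit associations, plus hooks to train
the transfer classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import ClusterClassifier, train_classifier
from .io import ClinicalTable, ExpressionMatrix, GeneSignature, ValidationError
from .selection import ClusterAssignment, hcluster, label_clusters
from .stats import (cluster_benefit_association, cox_multivariate,
                    derive_benefit_table, encode_cluster_labels, km_curves,
                    logrank_test)


class APMClusterModel:
    """Four-cluster APM model over one cohort.

    Parameters
    ----------
    expression
        Genes × samples matrix; MHC class I genes should already be
        purity-corrected (``corrected-TPM``), class II genes left raw.
    signature
        The APM gene signature used for clustering (defaults to the
        23-gene published signature).
    clinical
        Optional survival/response table aligned on sample ids.
    k, distance, linkage
        Clustering controls; four clusters with complete linkage on
        Euclidean distances of log2(TPM+1) by default.
    """

    def __init__(self, expression: ExpressionMatrix,
                 signature: GeneSignature | Sequence[str] | None = None,
                 clinical: ClinicalTable | None = None, k: int = 4,
                 distance: str = "euclidean", linkage: str = "complete",
                 missing_genes: str = "error"):
        if isinstance(signature, GeneSignature) or signature is None:
            sig = signature or GeneSignature.default()
            self.signature_genes = list(sig.final_genes)
            self.signature = sig
        else:
            self.signature_genes = list(signature)
            self.signature = None
        self.expression = expression
        self.clinical = clinical
        self.k = k
        self.distance = distance
        self.linkage = linkage
        self.missing_genes = missing_genes
        if clinical is not None:
            missing = [s for s in expression.sample_ids
                       if s not in clinical.sample_ids]
            if missing:
                raise ValidationError(
                    f"samples without clinical data: {missing[:5]}")

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, unit_tag: str = "TPM",
                       **kw) -> "APMClusterModel":
        """Build from a raw genes × samples DataFrame."""
        return cls(ExpressionMatrix(frame, unit_tag=unit_tag), **kw)

    def fit(self) -> "APMClusterResults":
        assignment = hcluster(self.expression, self.signature_genes,
                              k=self.k, distance=self.distance,
                              linkage=self.linkage,
                              missing=self.missing_genes)
        if self.k == 4:
            assignment = label_clusters(assignment, self.expression,
                                        self.signature_genes, self.clinical)
        return APMClusterResults(model=self, assignment=assignment)


@dataclass
class APMClusterResults:
    """Fitted four-cluster assignment with outcome summaries."""

    model: APMClusterModel
    assignment: ClusterAssignment
    _logrank: object = field(default=None, repr=False)

    @property
    def labels(self) -> pd.Series:
        return self.assignment.labels

    def logrank(self):
        """k-group log-rank test of the clusters against survival."""
        clin = self._require_clinical()
        if self._logrank is None:
            joint = self.labels.loc[clin.sample_ids]
            self._logrank = logrank_test(clin.time, clin.event, joint)
        return self._logrank

    def km(self) -> dict:
        clin = self._require_clinical()
        joint = self.labels.loc[clin.sample_ids]
        return km_curves(clin.time, clin.event, joint)

    def cox(self, covariates: Sequence[str] | None = None):
        """Multivariate Cox fit with the cluster coding C1=1 … C4=4."""
        clin = self._require_clinical()
        coded = encode_cluster_labels(self.labels.loc[clin.sample_ids])
        extra = coded.to_frame()
        cols = ["apm_cluster"] + list(covariates or [])
        return cox_multivariate(clin, cols, extra=extra)

    def benefit_association(self) -> dict:
        clin = self._require_clinical()
        benefit = derive_benefit_table(clin)
        return cluster_benefit_association(self.labels, benefit)

    def train_classifier(self, seed: int = 0, **hyper) -> ClusterClassifier:
        """Train the transfer classifier on this cohort's labels."""
        return train_classifier([(self.model.expression, self.assignment)],
                                self.model.signature_genes, seed=seed,
                                **hyper)

    def summary(self) -> pd.DataFrame:
        """Per-cluster table: n, mean signature expression, survival."""
        expr = self.model.expression.subset_genes(self.model.signature_genes,
                                                  missing="drop")
        score = np.log2(expr.values + 1.0).mean(axis=0)
        rows = []
        km = None
        logrank_p = None
        if self.model.clinical is not None:
            km = self.km()
            logrank_p = self.logrank().p_value
        for cluster in sorted(self.labels.unique()):
            members = self.labels.index[self.labels == cluster]
            row = {"cluster": cluster, "n": len(members),
                   "mean_signature_log2tpm": float(score[members].mean())}
            if km is not None and cluster in km:
                row["median_survival"] = km[cluster]["median"]
            rows.append(row)
        out = pd.DataFrame(rows).set_index("cluster")
        out.attrs["logrank_p"] = logrank_p
        return out

    def _require_clinical(self) -> ClinicalTable:
        if self.model.clinical is None:
            raise ValidationError("no clinical table attached to the model")
        return self.model.clinical

    def plot_km(self, ax=None):
        """Kaplan–Meier curves per cluster (matplotlib axes)."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        for cluster, curve in self.km().items():
            ax.step(curve["timeline"], curve["survival"], where="post",
                    label=f"{cluster} (n={curve['n']})")
        ax.set_xlabel(f"time ({self.model.clinical.time_unit})")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.02)
        ax.legend()
        return ax
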