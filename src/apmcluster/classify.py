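"""Cluster-label transfer: HG7 normalization + multinomial logistic regression.

To move the four APM clusters from the discovery cohorts onto new bulk or
single-cell (pseudobulk) cohorts, signature-gene expression is first put on
a cohort-comparable scale with a seven-housekeeping-gene (HG7) score: each
patient's HG7 score is log2(mean TPM of the housekeeping genes + 1), the
cohort scalar is the mean of those scores, and log2(TPM+1) of every
signature gene is divided by that scalar.  A multinomial logistic
regression (saga solver, C = 8, up to 1500 iterations — chosen on the
training set) then maps the normalized features to C1–C4.  Performance is
summarized as the micro-averaged one-vs-rest AUC under repeated stratified
tenfold cross-validation.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import label_binarize

from . import genesets
from .io import ExpressionMatrix, ValidationError
from .purity import PseudobulkProfiles
from .selection import ClusterAssignment

logger = logging.getLogger("apmcluster")

CLASSES = ("C1", "C2", "C3", "C4")


def hg7_normalize(expr: ExpressionMatrix, signature_genes: Sequence[str],
                  hk_genes: Sequence[str] | None = None) -> pd.DataFrame:
    """Housekeeping-normalized feature matrix (samples × signature genes).

    Per patient, HG7 score = log2(mean TPM of the housekeeping genes + 1);
    the cohort scalar is the mean score over patients; features are
    log2(TPM+1) of the signature genes divided by the scalar.  The division
    acts on the log scale, so a cohort-wide multiplicative shift of the
    housekeeping genes rescales all features uniformly.
    """
    hk = list(hk_genes if hk_genes is not None else genesets.HG7_GENES)
    missing = [g for g in hk if g not in expr.values.index]
    if missing:
        raise ValidationError(f"housekeeping genes missing: {missing}")
    scores = np.log2(expr.values.loc[hk].mean(axis=0) + 1.0)
    scalar = float(scores.mean())
    if scalar <= 0:
        raise ValidationError(
            "cohort housekeeping scalar is non-positive "
            "(all-zero housekeeping expression?)")
    sig = expr.subset_genes(list(signature_genes))
    features = np.log2(sig.values + 1.0).T / scalar
    return features


@dataclass
class ClusterClassifier:
    """Multinomial logistic-regression transfer model for the APM clusters.

    Estimator-style: :meth:`fit` on HG7-normalized features and C1–C4
    labels, :meth:`predict`/:meth:`predict_proba` on new feature matrices,
    and :meth:`cross_validate` for the repeated tenfold micro-AUC.  The
    feature gene order is fixed at fit time and enforced at prediction.
    """

    signature_genes: tuple[str, ...]
    hk_genes: tuple[str, ...] = tuple(genesets.HG7_GENES)
    C: float = 8.0
    max_iter: int = 1500
    solver: str = "saga"
    seed: int = 0
    estimator: LogisticRegression = field(default=None, repr=False)
    classes_: tuple[str, ...] = field(default=None, repr=False)
    training_meta: dict = field(default_factory=dict, repr=False)

    # -- fitting ----------------------------------------------------------
    def fit(self, features: pd.DataFrame, labels: pd.Series
            ) -> "ClusterClassifier":
        """Fit on samples × signature-gene features and cluster labels."""
        X, y = self._check_xy(features, labels)
        if len(np.unique(y)) < 2:
            raise ValidationError("training labels contain a single class")
        est = LogisticRegression(solver=self.solver, C=self.C,
                                 max_iter=self.max_iter,
                                 random_state=self.seed)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            est.fit(X, y)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            logger.warning("logistic regression hit the iteration cap "
                           "(max_iter=%d) before convergence", self.max_iter)
        self.estimator = est
        self.classes_ = tuple(est.classes_)
        self.training_meta = {"n_samples": int(X.shape[0]),
                              "seed": self.seed}
        return self

    def _check_xy(self, features: pd.DataFrame, labels: pd.Series | None):
        cols = list(features.columns)
        if cols != list(self.signature_genes):
            missing = [g for g in self.signature_genes if g not in cols]
            if missing:
                raise ValidationError(f"feature genes missing: {missing}")
            features = features[list(self.signature_genes)]
        X = features.to_numpy(dtype=float)
        if not np.isfinite(X).all():
            raise ValidationError("non-finite feature values")
        if labels is None:
            return X, None
        y = np.asarray(labels.loc[features.index])
        return X, y

    # -- prediction -------------------------------------------------------
    def predict_proba(self, features: pd.DataFrame) -> pd.DataFrame:
        if self.estimator is None:
            raise ValidationError("classifier is not fitted")
        X, _ = self._check_xy(features, None)
        proba = self.estimator.predict_proba(X)
        return pd.DataFrame(proba, index=features.index,
                            columns=list(self.classes_))

    def predict(self, features: pd.DataFrame) -> ClusterAssignment:
        proba = self.predict_proba(features)
        labels = proba.idxmax(axis=1)
        labels.name = "cluster"
        return ClusterAssignment(labels=labels, k=len(self.classes_))

    # -- evaluation -------------------------------------------------------
    def cross_validate(self, features: pd.DataFrame, labels: pd.Series,
                       folds: int = 10, repeats: int = 50,
                       seed: int | None = None) -> np.ndarray:
        """Repeated stratified k-fold micro-averaged one-vs-rest AUC.

        Each repeat pools the out-of-fold class probabilities over all
        samples and computes one micro-AUC; returns one value per repeat.
        ``repeats`` defaults to 50 for speed and accepts the full 1000.
        """
        X, y = self._check_xy(features, labels)
        class_counts = pd.Series(y).value_counts()
        if (class_counts < folds).any():
            small = class_counts[class_counts < folds]
            raise ValidationError(
                f"classes with fewer members than folds={folds}: "
                f"{dict(small)}; reduce the number of folds")
        rng = np.random.default_rng(self.seed if seed is None else seed)
        classes = np.unique(y)
        aucs = np.empty(repeats)
        for r in range(repeats):
            skf = StratifiedKFold(n_splits=folds, shuffle=True,
                                  random_state=int(rng.integers(2**31)))
            oof = np.zeros((len(y), len(classes)))
            for train_idx, test_idx in skf.split(X, y):
                est = LogisticRegression(solver=self.solver, C=self.C,
                                         max_iter=self.max_iter,
                                         random_state=self.seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    est.fit(X[train_idx], y[train_idx])
                proba = est.predict_proba(X[test_idx])
                for j, cls in enumerate(est.classes_):
                    oof[test_idx, np.searchsorted(classes, cls)] = proba[:, j]
            y_bin = label_binarize(y, classes=classes)
            if y_bin.shape[1] == 1:  # binary case
                y_bin = np.hstack([1 - y_bin, y_bin])
            aucs[r] = roc_auc_score(y_bin, oof, average="micro")
        return aucs

    # -- persistence ------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        """Serialize genes, coefficients and hyperparameters as JSON."""
        if self.estimator is None:
            raise ValidationError("classifier is not fitted")
        payload = {
            "signature_genes": list(self.signature_genes),
            "hk_genes": list(self.hk_genes),
            "classes": list(self.classes_),
            "coef": self.estimator.coef_.tolist(),
            "intercept": self.estimator.intercept_.tolist(),
            "hyperparameters": {"solver": self.solver, "C": self.C,
                                "max_iter": self.max_iter},
            "seed": self.seed,
            "training_meta": self.training_meta,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClusterClassifier":
        payload = json.loads(Path(path).read_text())
        hp = payload["hyperparameters"]
        obj = cls(signature_genes=tuple(payload["signature_genes"]),
                  hk_genes=tuple(payload["hk_genes"]), C=hp["C"],
                  max_iter=hp["max_iter"], solver=hp["solver"],
                  seed=payload["seed"])
        est = LogisticRegression(solver=hp["solver"], C=hp["C"],
                                 max_iter=hp["max_iter"],
                                 random_state=payload["seed"])
        est.coef_ = np.asarray(payload["coef"])
        est.intercept_ = np.asarray(payload["intercept"])
        est.classes_ = np.asarray(payload["classes"])
        obj.estimator = est
        obj.classes_ = tuple(payload["classes"])
        obj.training_meta = payload.get("training_meta", {})
        return obj


# ---------------------------------------------------------------------------
# convenience wrappers
# ---------------------------------------------------------------------------

def train_classifier(cohorts: Sequence[tuple[ExpressionMatrix,
                                             ClusterAssignment]],
                     signature_genes: Sequence[str],
                     hk_genes: Sequence[str] | None = None,
                     seed: int = 0, **hyper) -> ClusterClassifier:
    """Train on one or more discovery cohorts.

    Each cohort is HG7-normalized with its own cohort scalar before the
    feature matrices are stacked, mirroring per-cohort batch correction.
    """
    hk = tuple(hk_genes if hk_genes is not None else genesets.HG7_GENES)
    feats, labs = [], []
    for expr, assignment in cohorts:
        f = hg7_normalize(expr, signature_genes, hk)
        feats.append(f)
        labs.append(assignment.labels.loc[f.index])
    features = pd.concat(feats, axis=0)
    labels = pd.concat(labs, axis=0)
    clf = ClusterClassifier(signature_genes=tuple(signature_genes),
                            hk_genes=hk, seed=seed, **hyper)
    return clf.fit(features, labels)


def predict_clusters(model: ClusterClassifier,
                     new_data: ExpressionMatrix | PseudobulkProfiles,
                     mode: str = "bulk") -> tuple[ClusterAssignment,
                                                  pd.DataFrame]:
    """Transfer cluster labels to a new cohort.

    ``mode="bulk"``: features come straight from the bulk matrix,
    HG7-normalized with the new cohort's own scalar.  ``mode=
    "pseudobulk-sc"``: class I pathway features come from the
    malignant-cell pseudobulk, class II features from the non-malignant
    pseudobulk, and the housekeeping scalar from the all-cell pseudobulk.
    """
    if mode == "bulk":
        if not isinstance(new_data, ExpressionMatrix):
            raise ValidationError("bulk mode expects an ExpressionMatrix")
        features = hg7_normalize(new_data, model.signature_genes,
                                 model.hk_genes)
    elif mode == "pseudobulk-sc":
        if not isinstance(new_data, PseudobulkProfiles):
            raise ValidationError(
                "pseudobulk-sc mode expects PseudobulkProfiles")
        hk = list(model.hk_genes)
        missing = [g for g in hk if g not in new_data.all_cells.index]
        if missing:
            raise ValidationError(f"housekeeping genes missing: {missing}")
        scores = np.log2(new_data.all_cells.loc[hk].mean(axis=0) + 1.0)
        scalar = float(scores.mean())
        if scalar <= 0:
            raise ValidationError("non-positive housekeeping scalar")
        patients = [p for p in new_data.malignant.columns
                    if p in new_data.non_malignant.columns]
        rows = {}
        for gene in model.signature_genes:
            source = (new_data.non_malignant
                      if genesets.is_mhc_class_ii(gene)
                      else new_data.malignant)
            if gene not in source.index:
                raise ValidationError(f"feature gene {gene!r} missing from "
                                      "pseudobulk")
            rows[gene] = np.log2(source.loc[gene, patients].astype(float)
                                 + 1.0) / scalar
        features = pd.DataFrame(rows, index=patients)
    else:
        raise ValidationError(f"unknown prediction mode {mode!r}")
    proba = model.predict_proba(features)
    assignment = model.predict(features)
    return assignment, proba
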