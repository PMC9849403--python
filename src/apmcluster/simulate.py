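"""Synthetic single-cell and bulk cohorts with known ground truth.

The generators emulate the statistical structure the analysis assumes —
not real scRNA-seq chemistry.  A single-cell cohort draws per-cell TPM
log-normally around compartment means whose non-malignant/malignant ratio
is the planted normalization factor N_x.  A bulk cohort plants a four-group
APM expression structure, builds each bulk profile as the purity-weighted
mixture beta = gamma*p + lambda*(1-p) with lambda = N_x*gamma (times
multiplicative noise), draws exponential survival with a per-cluster hazard
under administrative censoring, and draws RECIST-style best-overall-response
labels from cluster-specific categorical probabilities.  ESTIMATE scores
are emitted by inverting the cosine purity transform so the purity path is
testable end to end.

All randomness flows from one ``numpy.random.default_rng(seed)`` per call;
identical parameters and seed give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd

from . import genesets
from .io import (CellTable, ClinicalTable, ExpressionMatrix, GeneSignature,
                 ValidationError)
from .purity import purity_to_estimate_score

#: default per-cluster multiplicative APM shifts (cluster 1 hottest)
DEFAULT_EFFECT_SIZES = (6.0, 3.0, 1.0, 0.3)
#: default exponential hazards per cluster, events per month
DEFAULT_HAZARDS = (0.02, 0.05, 0.08, 0.2)
#: default best-overall-response probabilities per cluster
#: (CRPR, SD, MR, PD, NE)
DEFAULT_RESPONSE_PROBS = (
    (0.60, 0.20, 0.05, 0.10, 0.05),
    (0.35, 0.25, 0.05, 0.30, 0.05),
    (0.25, 0.25, 0.05, 0.40, 0.05),
    (0.05, 0.15, 0.05, 0.70, 0.05),
)
BOR_CATEGORIES = ("CRPR", "SD", "MR", "PD", "NE")


@dataclass
class SyntheticTruth:
    """Ground truth carried alongside a synthetic cohort."""

    mu_malignant: pd.Series | None = None
    mu_nonmalignant: pd.Series | None = None
    norm_factors: pd.Series | None = None
    purity: pd.Series | None = None
    cluster_labels: pd.Series | None = None
    hazards: tuple | None = None
    informative_genes: tuple[str, ...] = ()
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        def ser(x):
            if isinstance(x, pd.Series):
                return {str(k): (v if not isinstance(v, float) else float(v))
                        for k, v in x.items()}
            return x
        payload = {k: ser(v) for k, v in dataclasses.asdict(self).items()
                   if not isinstance(v, pd.Series)}
        for name in ("mu_malignant", "mu_nonmalignant", "norm_factors",
                     "purity", "cluster_labels"):
            val = getattr(self, name)
            if val is not None:
                payload[name] = {str(k): (float(v) if np.isreal(v) and
                                          not isinstance(v, str) else v)
                                 for k, v in val.items()}
        Path(path).write_text(json.dumps(payload, indent=1, default=str))


def _lognormal_noise(rng: np.random.Generator, sigma: float,
                     size) -> np.ndarray:
    """Multiplicative noise with mean 1 (log-normal, heavy right tail)."""
    if sigma == 0:
        return np.ones(size)
    return np.exp(rng.normal(-sigma ** 2 / 2.0, sigma, size=size))


def _default_gene_panel() -> list[str]:
    panel = list(dict.fromkeys(
        genesets.MHC_I_CORRECTION_GENES + genesets.BASE_GENES
        + genesets.ADDITIONAL_CANDIDATES + genesets.HG7_GENES
        + genesets.CYT_GENES))
    panel += [f"FILLER{i:02d}" for i in range(1, 21)]
    return panel


# ---------------------------------------------------------------------------
# single-cell cohort
# ---------------------------------------------------------------------------

def generate_sc_cohort(n_patients: int = 20, cells_per_patient: int = 200,
                       gene_panel: Sequence[str] | None = None,
                       apm_ratio: Mapping[str, float] | float = 3.0,
                       dispersion: float = 0.3,
                       undefined_frac: float = 0.05,
                       purity_range: tuple[float, float] = (0.3, 0.7),
                       seed: int = 0) -> tuple[CellTable, SyntheticTruth]:
    """Synthetic single-cell cohort with malignant/non-malignant structure.

    ``apm_ratio`` gives the planted N_x (non-malignant over malignant mean)
    per MHC-I gene — a scalar applies to the whole correction gene set;
    genes without a ratio share the same mean in both compartments.  Cell
    TPM is drawn log-normally (mean-preserving) around the compartment mean
    with log-scale standard deviation ``dispersion``; ``dispersion=0``
    reproduces the means exactly.  A fraction of cells per patient is
    labelled ``undefined``.
    """
    if cells_per_patient < 2:
        raise ValidationError("need at least 2 cells per patient")
    rng = np.random.default_rng(seed)
    genes = list(gene_panel) if gene_panel is not None else _default_gene_panel()
    if isinstance(apm_ratio, (int, float)):
        if apm_ratio <= 0:
            raise ValidationError("apm_ratio must be positive")
        ratios = {g: float(apm_ratio) for g in genesets.MHC_I_CORRECTION_GENES
                  if g in genes}
    else:
        ratios = {g: float(v) for g, v in apm_ratio.items()}
        if any(v <= 0 for v in ratios.values()):
            raise ValidationError("apm_ratio must be positive")
        missing = [g for g in ratios if g not in genes]
        if missing:
            raise ValidationError(f"ratio genes absent from panel: {missing}")
    mu_mal = pd.Series(np.exp(rng.uniform(np.log(10), np.log(200),
                                          len(genes))), index=genes)
    n_factor = pd.Series({g: ratios.get(g, 1.0) for g in genes})
    mu_non = mu_mal * n_factor

    rows, cell_ids, patients, ctypes = [], [], [], []
    truth_purity = {}
    for i in range(n_patients):
        pid = f"P{i + 1:02d}"
        n_undef = int(round(undefined_frac * cells_per_patient))
        n_annot = cells_per_patient - n_undef
        if n_annot < 2:
            raise ValidationError("undefined fraction leaves <2 annotated "
                                  "cells per patient")
        p = rng.uniform(*purity_range)
        n_mal = int(np.clip(round(p * n_annot), 1, n_annot - 1))
        n_non = n_annot - n_mal
        truth_purity[pid] = n_mal / n_annot
        for comp, n_cells, mu in (("malignant", n_mal, mu_mal),
                                  ("non-malignant", n_non, mu_non),
                                  ("undefined", n_undef, mu_non)):
            if n_cells == 0:
                continue
            noise = _lognormal_noise(rng, dispersion, (n_cells, len(genes)))
            rows.append(mu.to_numpy()[None, :] * noise)
            for j in range(n_cells):
                cell_ids.append(f"{pid}_{comp[:3]}{j + 1:03d}")
                patients.append(pid)
                ctypes.append(comp)
    X = np.vstack(rows)
    obs = pd.DataFrame({"patient_id": patients, "cell_type": ctypes},
                       index=cell_ids)
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=genes))
    truth = SyntheticTruth(mu_malignant=mu_mal, mu_nonmalignant=mu_non,
                           norm_factors=pd.Series(ratios),
                           purity=pd.Series(truth_purity), seed=seed)
    return CellTable(adata), truth


# ---------------------------------------------------------------------------
# bulk cohort
# ---------------------------------------------------------------------------

def generate_bulk_cohort(n_samples: int = 160,
                         signature: GeneSignature | None = None,
                         cluster_effect_sizes: Sequence[float]
                         = DEFAULT_EFFECT_SIZES,
                         truth_factors: Mapping[str, float] | float = 3.0,
                         purity_range: tuple[float, float] = (0.2, 0.8),
                         hazard_per_cluster: Sequence[float]
                         = DEFAULT_HAZARDS,
                         response_probs_per_cluster: Sequence[Sequence[float]]
                         = DEFAULT_RESPONSE_PROBS,
                         noise_sd: float = 0.25,
                         censor_horizon_months: float = 36.0,
                         gene_panel: Sequence[str] | None = None,
                         sample_prefix: str = "S",
                         seed: int = 0
                         ) -> tuple[ExpressionMatrix, ClinicalTable,
                                    pd.Series, SyntheticTruth]:
    """Bulk cohort with a planted four-group APM structure.

    Per sample: a cluster is drawn uniformly; the malignant profile gamma
    of each signature gene is its baseline mean times the cluster's effect
    size times log-normal noise; lambda = N_x * gamma (times noise) for
    genes carrying a normalization factor; beta mixes the two by a purity
    drawn from ``purity_range``.  Survival is exponential with the
    cluster's hazard (per month), administratively censored at
    ``censor_horizon_months``; best overall response is categorical per
    cluster.  The clinical table carries the ESTIMATE score implied by the
    true purity.
    """
    hazards = tuple(float(h) for h in hazard_per_cluster)
    if any(h <= 0 for h in hazards):
        raise ValidationError("hazards must be positive")
    effects = tuple(float(e) for e in cluster_effect_sizes)
    n_clusters = len(effects)
    if len(hazards) != n_clusters:
        raise ValidationError("one hazard per cluster required")
    if len(set(effects)) != n_clusters:
        raise ValidationError("cluster effect sizes must be distinct")
    rng = np.random.default_rng(seed)
    sig = signature or GeneSignature.default()
    genes = list(gene_panel) if gene_panel is not None else _default_gene_panel()
    missing = [g for g in sig.final_genes if g not in genes]
    if missing:
        raise ValidationError(f"signature genes absent from panel: {missing}")
    if isinstance(truth_factors, (int, float)):
        factors = pd.Series({g: float(truth_factors)
                             for g in genesets.MHC_I_CORRECTION_GENES
                             if g in genes})
    else:
        factors = pd.Series({g: float(v) for g, v in truth_factors.items()})
    n_vec = pd.Series(1.0, index=genes)
    n_vec.loc[factors.index] = factors

    mu = pd.Series(np.exp(rng.uniform(np.log(20), np.log(150), len(genes))),
                   index=genes)
    clusters = rng.integers(1, n_clusters + 1, size=n_samples)
    purity = rng.uniform(*purity_range, size=n_samples)
    sample_ids = [f"{sample_prefix}{i + 1:03d}" for i in range(n_samples)]

    sig_mask = np.array([g in sig.final_genes for g in genes])
    effect_per_sample = np.array([effects[c - 1] for c in clusters])
    gamma = np.tile(mu.to_numpy()[:, None], (1, n_samples))
    gamma[sig_mask, :] *= effect_per_sample[None, :]
    gamma *= _lognormal_noise(rng, noise_sd, gamma.shape)
    lam = n_vec.to_numpy()[:, None] * gamma \
        * _lognormal_noise(rng, noise_sd, gamma.shape)
    beta = gamma * purity[None, :] + lam * (1.0 - purity[None, :])

    raw_times = rng.exponential(
        1.0 / np.array([hazards[c - 1] for c in clusters]))
    event = (raw_times <= censor_horizon_months).astype(int)
    times = np.maximum(np.minimum(raw_times, censor_horizon_months), 1e-6)

    probs = np.asarray(response_probs_per_cluster, dtype=float)
    if probs.shape != (n_clusters, len(BOR_CATEGORIES)):
        raise ValidationError("response_probs_per_cluster must be "
                              f"{n_clusters}×{len(BOR_CATEGORIES)}")
    bor = [BOR_CATEGORIES[rng.choice(len(BOR_CATEGORIES),
                                     p=probs[c - 1] / probs[c - 1].sum())]
           for c in clusters]

    purity_s = pd.Series(purity, index=sample_ids, name="purity")
    expr = ExpressionMatrix(pd.DataFrame(beta, index=genes,
                                         columns=sample_ids), "TPM")
    clin = pd.DataFrame({
        "time": times, "event": event, "bor": bor,
        "estimate_score": purity_to_estimate_score(purity),
        "tmb": rng.lognormal(2.0, 1.0, n_samples).round(1),
        "prior_ipi": rng.integers(0, 2, n_samples),
    }, index=sample_ids)
    clin.index.name = "sample"
    clinical = ClinicalTable(clin, time_unit="months")
    truth = SyntheticTruth(
        mu_malignant=mu, norm_factors=factors, purity=purity_s,
        cluster_labels=pd.Series(clusters, index=sample_ids, name="cluster"),
        hazards=hazards, seed=seed)
    # gamma on the truth side, for mixture-inversion tests
    truth.mu_nonmalignant = pd.Series((mu * n_vec), index=genes)
    truth.gamma = pd.DataFrame(gamma, index=genes, columns=sample_ids)
    return expr, clinical, purity_s, truth


# ---------------------------------------------------------------------------
# planted selection scenario
# ---------------------------------------------------------------------------

def plant_selection_scenario(base_genes: Sequence[str] | None = None,
                             n_candidates: int = 8, n_informative: int = 3,
                             n_samples: int = 150, n_cohorts: int = 2,
                             effect: float = 16.0,
                             hazard_per_cluster: Sequence[float]
                             = (0.01, 0.05, 0.15, 0.50),
                             noise_sd: float = 0.25,
                             seed: int = 0
                             ) -> tuple[list[tuple[ExpressionMatrix,
                                                   ClinicalTable]],
                                        SyntheticTruth]:
    """Cohorts where only a known candidate subset separates the clusters.

    The base genes are expressed but carry no cluster signal; informative
    candidate gene *j* is elevated ``effect``-fold in planted cluster *j*
    only (one-vs-rest coding), so every informative gene is necessary:
    dropping gene *j* merges cluster *j* into the baseline group and
    degrades the survival separation.  The remaining candidates are pure
    noise.  Survival hazards depend on the planted cluster, so clustering
    on base ∪ (informative set) stratifies survival while noise genes only
    dilute it.  Truth records the informative set.
    """
    if n_informative > n_candidates:
        raise ValidationError("n_informative cannot exceed n_candidates")
    base = list(base_genes) if base_genes is not None \
        else [f"BASE{i:02d}" for i in range(1, 5)]
    candidates = [f"ADD{i:02d}" for i in range(1, n_candidates + 1)]
    informative = tuple(candidates[:n_informative])
    rng = np.random.default_rng(seed)
    genes = base + candidates
    hazards = tuple(float(h) for h in hazard_per_cluster)
    if any(h <= 0 for h in hazards):
        raise ValidationError("hazards must be positive")
    n_clusters = len(hazards)
    cohorts = []
    truth_labels = {}
    for c_idx in range(n_cohorts):
        mu = pd.Series(np.exp(rng.uniform(np.log(20), np.log(150),
                                          len(genes))), index=genes)
        clusters = rng.integers(1, n_clusters + 1, size=n_samples)
        expr = np.tile(mu.to_numpy()[:, None], (1, n_samples))
        for j, gene in enumerate(informative):
            target = (j % n_clusters) + 1
            gi = genes.index(gene)
            expr[gi, clusters == target] *= float(effect)
        expr *= _lognormal_noise(rng, noise_sd, expr.shape)
        sample_ids = [f"K{c_idx + 1}_{i + 1:03d}" for i in range(n_samples)]
        raw_times = rng.exponential(
            1.0 / np.array([hazards[c - 1] for c in clusters]))
        horizon = 60.0
        event = (raw_times <= horizon).astype(int)
        times = np.maximum(np.minimum(raw_times, horizon), 1e-6)
        clinical = ClinicalTable(pd.DataFrame(
            {"time": times, "event": event},
            index=pd.Index(sample_ids, name="sample")), time_unit="months")
        cohorts.append((ExpressionMatrix(
            pd.DataFrame(expr, index=genes, columns=sample_ids), "TPM"),
            clinical))
        truth_labels.update(dict(zip(sample_ids, clusters)))
    truth = SyntheticTruth(
        cluster_labels=pd.Series(truth_labels, name="cluster"),
        hazards=hazards, informative_genes=informative, seed=seed)
    truth.base_genes = tuple(base)
    truth.candidate_genes = tuple(candidates)
    return cohorts, truth
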