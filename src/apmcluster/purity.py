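"""Tumor-purity correction of bulk MHC class I expression.

MHC class I pathway genes are expressed by both malignant and non-malignant
cells, and usually more highly by the latter, so a bulk profile overstates
tumor-intrinsic antigen presentation.  The bulk expression of gene *x* in
sample *i* is modelled as a purity-weighted mixture

    beta_{x,i} = gamma_{x,i} * p_i + lambda_{x,i} * (1 - p_i)

of the malignant profile gamma and the non-malignant profile lambda.  A
single-cell cohort supplies a cohort-wide normalization factor per gene,

    N_x = sum_i lambda_{x,i} / sum_i gamma_{x,i}

(patient-level pseudobulk sums).  Under lambda = N_x * gamma the mixture is
invertible and the tumor-specific expression is

    gamma_{x,i} = beta_{x,i} / (p_i + N_x - N_x * p_i).

Class II genes are expressed by immune cells and are left uncorrected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import genesets
from .io import CellTable, ExpressionMatrix, ValidationError

logger = logging.getLogger("apmcluster")

#: Guard for the mixture denominator p + N - N*p (only small when both the
#: purity and the normalization factor are near zero).
DENOMINATOR_EPS = 1e-9


@dataclass(frozen=True)
class PurityConstants:
    """Constants of the ESTIMATE-score → purity cosine transform.

    ``purity = cos(intercept + slope * score)``; the defaults are the
    published calibration (radians, radians per score unit).
    """

    intercept: float = 0.6049872018
    slope: float = 0.0001467884


@dataclass
class PseudobulkProfiles:
    """Per-patient pseudobulk profiles split by compartment.

    Each frame is genes × patients (arithmetic mean TPM over the cells of
    that compartment); ``purity`` is the malignant cell fraction among the
    annotated (non-"undefined") cells.  Patients with no cell in a
    compartment are absent from that frame.
    """

    all_cells: pd.DataFrame
    malignant: pd.DataFrame
    non_malignant: pd.DataFrame
    purity: pd.Series


def qc_filter_sc(cells: CellTable, min_total_reads: int = 5,
                 stress_gene_list: Sequence[str] | None = None) -> CellTable:
    """Drop low-coverage and dissociation-stress genes; cells are untouched.

    Genes with fewer than ``min_total_reads`` reads summed over all cells
    are excluded, as are any genes on ``stress_gene_list``.
    """
    frame = cells.to_frame()
    totals = frame.sum(axis=0)
    keep = totals >= min_total_reads
    if stress_gene_list:
        keep &= ~frame.columns.isin(list(stress_gene_list))
    if not keep.any():
        raise ValidationError("no genes survive quality-control filtering")
    filtered = cells.adata[:, keep.to_numpy()].copy()
    logger.info("QC kept %d/%d genes", int(keep.sum()), len(keep))
    return CellTable(filtered)


def compute_pseudobulk(cells: CellTable,
                       compartment: str = "all") -> pd.DataFrame:
    """Patient-level pseudobulk: mean TPM across a compartment's cells.

    ``compartment`` is ``"all"`` (every annotated cell), ``"malignant"`` or
    ``"non-malignant"``.  Cells annotated ``"undefined"`` are always
    excluded.  Patients with no qualifying cell are omitted with a warning.
    Returns genes × patients.
    """
    frame = cells.to_frame()
    ctype = cells.cell_type.astype(str)
    defined = ctype != "undefined"
    if compartment == "all":
        mask = defined
    elif compartment == "malignant":
        mask = defined & (ctype == "malignant")
    elif compartment == "non-malignant":
        mask = defined & (ctype != "malignant")
    else:
        raise ValueError(f"unknown compartment {compartment!r}")
    if not mask.any():
        raise ValidationError(f"no cells in compartment {compartment!r}")
    sub = frame.loc[mask.to_numpy()]
    patients = cells.patient_ids[mask.to_numpy()]
    omitted = set(cells.patient_ids.unique()) - set(patients.unique())
    if omitted:
        logger.warning("patients without %s cells omitted: %s",
                       compartment, sorted(omitted))
    pb = sub.groupby(patients.to_numpy()).mean().T
    pb.columns = pb.columns.astype(str)
    return pb


def sc_purity(cells: CellTable) -> pd.Series:
    """Single-cell tumor purity: malignant fraction of annotated cells."""
    ctype = cells.cell_type.astype(str)
    defined = ctype != "undefined"
    out = {}
    for patient, sub in ctype[defined.to_numpy()].groupby(
            cells.patient_ids[defined.to_numpy()].to_numpy()):
        n = len(sub)
        if n == 0:
            raise ValidationError(f"patient {patient!r} has no annotated cells")
        out[str(patient)] = float((sub == "malignant").sum()) / n
    missing = set(cells.patient_ids.astype(str)) - set(out)
    if missing:
        raise ValidationError(
            f"patients with no annotated cells: {sorted(missing)}")
    return pd.Series(out, name="purity")


def estimate_score_to_purity(score, constants: PurityConstants | None = None):
    """ESTIMATE score → tumor purity via the cosine calibration.

    ``purity = cos(a + b*score)``.  Arguments outside [0, pi/2] are clamped
    (with a log warning) so purity stays in [0, 1]; extreme scores would
    otherwise map outside the unit interval.
    Accepts a scalar or array-like; returns the same shape.
    """
    c = constants or PurityConstants()
    score_arr = np.asarray(score, dtype=float)
    theta = c.intercept + c.slope * score_arr
    clipped = np.clip(theta, 0.0, math.pi / 2)
    if np.any(clipped != theta):
        logger.warning("ESTIMATE scores outside the valid cosine range "
                       "were clamped to keep purity in [0, 1]")
    out = np.cos(clipped)
    if np.isscalar(score) or score_arr.ndim == 0:
        return float(out)
    if isinstance(score, pd.Series):
        return pd.Series(out, index=score.index, name="purity")
    return out


def purity_to_estimate_score(purity, constants: PurityConstants | None = None):
    """Invert the cosine calibration (used to emit synthetic ESTIMATE scores)."""
    c = constants or PurityConstants()
    p = np.asarray(purity, dtype=float)
    score = (np.arccos(np.clip(p, 0.0, 1.0)) - c.intercept) / c.slope
    if np.isscalar(purity) or p.ndim == 0:
        return float(score)
    if isinstance(purity, pd.Series):
        return pd.Series(score, index=purity.index, name="estimate_score")
    return score


def build_pseudobulk_profiles(cells: CellTable) -> PseudobulkProfiles:
    """All-cell / malignant / non-malignant pseudobulk plus purity."""
    return PseudobulkProfiles(
        all_cells=compute_pseudobulk(cells, "all"),
        malignant=compute_pseudobulk(cells, "malignant"),
        non_malignant=compute_pseudobulk(cells, "non-malignant"),
        purity=sc_purity(cells),
    )


def compute_normalization_factors(
        profiles: PseudobulkProfiles,
        gene_set: Sequence[str] | None = None) -> pd.Series:
    """Cohort-wide N_x = Σ_i λ_{x,i} / Σ_i γ_{x,i} over shared patients.

    Only patients with at least one cell in *both* compartments contribute;
    dropping them from numerator and denominator symmetrically avoids
    biasing the ratio.  Raises if a gene has zero malignant expression
    across all contributing patients (N_x undefined).
    """
    genes = list(gene_set if gene_set is not None
                 else genesets.MHC_I_CORRECTION_GENES)
    missing = [g for g in genes if g not in profiles.malignant.index]
    if missing:
        raise ValidationError(f"genes absent from pseudobulk: {missing}")
    shared = [p for p in profiles.malignant.columns
              if p in profiles.non_malignant.columns]
    if not shared:
        raise ValidationError(
            "no patient has cells in both compartments; N_x undefined")
    lam = profiles.non_malignant.loc[genes, shared].sum(axis=1)
    gam = profiles.malignant.loc[genes, shared].sum(axis=1)
    zero = gam <= 0
    if zero.any():
        raise ValidationError(
            "zero malignant pseudobulk expression for "
            f"{list(gam.index[zero])}; normalization factor undefined")
    factors = lam / gam
    factors.name = "N_x"
    return factors


def correct_bulk_expression(bulk: ExpressionMatrix,
                            purity: pd.Series | Mapping[str, float],
                            factors: pd.Series | Mapping[str, float],
                            ) -> ExpressionMatrix:
    """Invert the purity mixture for the genes carrying a normalization factor.

    gamma = beta / (p + N - N*p), applied per gene-with-a-factor and per
    sample; all other genes (class II and everything else) pass through
    unchanged.  Output is tagged ``corrected-TPM``.
    """
    factors = pd.Series(dict(factors) if not isinstance(factors, pd.Series)
                        else factors)
    purity = pd.Series(dict(purity) if not isinstance(purity, pd.Series)
                       else purity)
    missing_s = [s for s in bulk.sample_ids if s not in purity.index]
    if missing_s:
        raise ValidationError(f"samples without purity: {missing_s[:5]}")
    missing_g = [g for g in factors.index if g not in bulk.values.index]
    if missing_g:
        raise ValidationError(
            f"correction genes absent from bulk matrix: {missing_g}")
    p = purity.loc[bulk.sample_ids].to_numpy(dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("purity values outside [0, 1]")
    n = factors.to_numpy(dtype=float)[:, None]
    denom = p[None, :] + n - n * p[None, :]
    if (denom <= DENOMINATOR_EPS).any():
        raise ValidationError(
            "mixture denominator p + N - N*p vanished (purity and "
            "normalization factor both near zero)")
    corrected = bulk.values.copy()
    corrected.loc[list(factors.index)] = (
        bulk.values.loc[list(factors.index)].to_numpy() / denom)
    return ExpressionMatrix(corrected, unit_tag="corrected-TPM")
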