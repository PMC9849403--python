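"""Domain containers and text-format I/O.

Expression lives in a genes × samples :class:`ExpressionMatrix` (TPM by
default), single-cell data in a :class:`CellTable` backed by
:class:`anndata.AnnData`, and clinical outcomes in a
:class:`ClinicalTable`.  All readers validate on load and refuse NaNs,
negative TPM values and duplicate identifiers; every writer/reader pair is
a lossless round trip on valid data.

On-disk formats are plain text: TSV/CSV with a header row of sample ids for
dense matrices, and matrix-market triplets with ``.rows``/``.cols``
companion name files for sparse single-cell matrices.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("apmcluster")

VALID_UNIT_TAGS = ("TPM", "corrected-TPM", "log2-TPM")
#: Controlled vocabulary for best overall response (RECIST-style).
BOR_VALUES = ("CRPR", "SD", "MR", "PD", "NE")
_BOR_ALIASES = {
    "CR": "CRPR", "PR": "CRPR", "CR/PR": "CRPR", "CRPR": "CRPR",
    "PRCR": "CRPR", "SD": "SD", "MR": "MR", "PD": "PD", "NE": "NE",
    "NA": None, "": None,
}


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass
class ExpressionMatrix:
    """Genes × samples expression matrix with a unit tag.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol with sample ids as columns.
    unit_tag
        One of ``TPM``, ``corrected-TPM`` or ``log2-TPM``; non-negativity
        is enforced for the first two.
    """

    values: pd.DataFrame
    unit_tag: str = "TPM"

    def __post_init__(self) -> None:
        if self.unit_tag not in VALID_UNIT_TAGS:
            raise ValidationError(
                f"unit_tag {self.unit_tag!r} not in {VALID_UNIT_TAGS}")
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][:5]
            raise ValidationError(f"duplicate gene symbols: {list(dup)}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][:5]
            raise ValidationError(f"duplicate sample ids: {list(dup)}")
        arr = self.values.to_numpy()
        if np.isnan(arr).any():
            g, s = np.argwhere(np.isnan(arr))[0]
            raise ValidationError(
                f"NaN at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}")
        if self.unit_tag in ("TPM", "corrected-TPM") and (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative value at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Sequence[str],
                     missing: str = "error") -> "ExpressionMatrix":
        """Select ``genes`` (in the given order).

        ``missing`` is ``"error"`` (default) or ``"drop"``; dropping logs a
        warning because silently losing signature genes changes clustering.
        """
        absent = [g for g in genes if g not in self.values.index]
        if absent:
            if missing == "drop":
                logger.warning("dropping %d missing genes: %s",
                               len(absent), absent)
                genes = [g for g in genes if g not in absent]
            else:
                raise ValidationError(f"genes missing from matrix: {absent}")
        return ExpressionMatrix(self.values.loc[list(genes)].copy(),
                                self.unit_tag)

    def log2p1(self) -> pd.DataFrame:
        """log2(x + 1) transform of the values (samples keep their columns)."""
        return np.log2(self.values + 1.0)

    def write(self, path: str | Path, sep: str = "\t") -> None:
        # %.17g round-trips float64 exactly
        self.values.to_csv(path, sep=sep, index_label="gene",
                           float_format="%.17g")


@dataclass
class CellTable:
    """Single-cell expression plus per-cell patient and cell-type labels.

    Backed by an :class:`anndata.AnnData` (cells × genes) whose ``obs``
    carries ``patient_id`` and ``cell_type``; the cell type is
    ``"malignant"``, a non-malignant label, or ``"undefined"``.
    """

    adata: ad.AnnData

    def __post_init__(self) -> None:
        for col in ("patient_id", "cell_type"):
            if col not in self.adata.obs:
                raise ValidationError(f"CellTable missing obs column {col!r}")
        if self.adata.n_obs == 0:
            raise ValidationError("CellTable has no cells")
        if len(set(self.adata.obs["patient_id"])) == 0:
            raise ValidationError("empty patient set")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.adata.obs_names)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.adata.var_names)

    @property
    def patient_ids(self) -> pd.Series:
        return self.adata.obs["patient_id"]

    @property
    def cell_type(self) -> pd.Series:
        return self.adata.obs["cell_type"]

    def to_frame(self) -> pd.DataFrame:
        """Dense cells × genes DataFrame of TPM values."""
        X = self.adata.X
        if scipy.sparse.issparse(X):
            X = X.toarray()
        return pd.DataFrame(np.asarray(X), index=self.adata.obs_names,
                            columns=self.adata.var_names)

    def write(self, prefix: str | Path) -> None:
        """Write as matrix-market triplet + name files + annotation TSV.

        Produces ``<prefix>.mtx`` (genes × cells), ``<prefix>.mtx.rows``
        (gene names), ``<prefix>.mtx.cols`` (cell names) and
        ``<prefix>.cells.tsv`` (cell, patient_id, cell_type).
        """
        prefix = Path(prefix)
        X = self.adata.X
        if not scipy.sparse.issparse(X):
            X = scipy.sparse.coo_matrix(np.asarray(X))
        scipy.io.mmwrite(str(prefix) + ".mtx", X.T.tocoo())
        Path(str(prefix) + ".mtx.rows").write_text(
            "\n".join(self.adata.var_names) + "\n")
        Path(str(prefix) + ".mtx.cols").write_text(
            "\n".join(self.adata.obs_names) + "\n")
        self.adata.obs[["patient_id", "cell_type"]].to_csv(
            str(prefix) + ".cells.tsv", sep="\t", index_label="cell")


@dataclass
class ClinicalTable:
    """Per-sample survival and response data.

    ``time`` is survival/follow-up time in the declared ``time_unit``
    (days or months — declared, never inferred), ``event`` is the usual
    0/1 indicator, ``bor`` the best overall response in the controlled
    vocabulary (or None), and any remaining columns are numeric/binary
    covariates.
    """

    data: pd.DataFrame
    time_unit: str = "months"

    def __post_init__(self) -> None:
        if self.time_unit not in ("days", "months"):
            raise ValidationError("time_unit must be 'days' or 'months'")
        for col in ("time", "event"):
            if col not in self.data:
                raise ValidationError(f"clinical table missing column {col!r}")
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample ids in clinical table")
        t = self.data["time"].astype(float)
        if (t <= 0).any() or t.isna().any():
            bad = self.data.index[(t <= 0) | t.isna()][:5]
            raise ValidationError(f"non-positive survival time for {list(bad)}")
        ev = self.data["event"]
        if not ev.isin([0, 1]).all():
            raise ValidationError("event must be 0 or 1")
        if "bor" in self.data:
            self.data["bor"] = [normalize_bor(b) for b in self.data["bor"]]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> pd.Series:
        return self.data["time"].astype(float)

    @property
    def event(self) -> pd.Series:
        return self.data["event"].astype(int)

    @property
    def bor(self) -> pd.Series:
        if "bor" not in self.data:
            return pd.Series(index=self.data.index, dtype=object)
        return self.data["bor"]

    def time_in_months(self) -> pd.Series:
        if self.time_unit == "months":
            return self.time
        return self.time / 30.44

    def covariates(self) -> pd.DataFrame:
        drop = [c for c in ("time", "event", "bor") if c in self.data]
        return self.data.drop(columns=drop)

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.data.to_csv(path, sep=sep, index_label="sample")


@dataclass
class GeneSignature:
    """Base gene list plus the selected additional APM features."""

    base_genes: tuple[str, ...]
    additional_candidates: tuple[str, ...] = ()
    selected_additional: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.base_genes = tuple(self.base_genes)
        self.additional_candidates = tuple(self.additional_candidates)
        self.selected_additional = tuple(self.selected_additional)
        extra = set(self.selected_additional) - set(self.additional_candidates)
        if extra:
            raise ValidationError(
                f"selected genes not among candidates: {sorted(extra)}")
        if len(set(self.base_genes)) != len(self.base_genes):
            raise ValidationError("duplicate base genes")

    @property
    def final_genes(self) -> tuple[str, ...]:
        """Base ∪ selected additional, order-preserving, duplicates removed."""
        seen: dict[str, None] = {}
        for g in self.base_genes + self.selected_additional:
            seen.setdefault(g, None)
        return tuple(seen)

    @classmethod
    def default(cls) -> "GeneSignature":
        from . import genesets
        return cls(genesets.BASE_GENES, genesets.ADDITIONAL_CANDIDATES,
                   genesets.SELECTED_ADDITIONAL)


def normalize_bor(value: object) -> str | None:
    """Map a raw best-overall-response string onto the controlled vocabulary."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    key = str(value).strip().upper().replace(" ", "")
    if key in _BOR_ALIASES:
        return _BOR_ALIASES[key]
    raise ValidationError(
        f"unknown best-overall-response value {value!r}; "
        f"allowed: {BOR_VALUES} (or CR/PR aliases, NA)")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, format: str | None = None,
                    unit_tag: str = "TPM",
                    transpose: bool = False) -> ExpressionMatrix:
    """Read a genes × samples expression matrix.

    ``format`` is ``tsv``, ``csv`` or ``mtx-triplet`` (inferred from the
    suffix when omitted).  The on-disk orientation is genes × samples with a
    header row of sample ids; set ``transpose`` when the file is samples ×
    genes — orientation is never guessed.
    """
    path = Path(path)
    if format is None:
        format = {".tsv": "tsv", ".txt": "tsv", ".csv": "csv",
                  ".mtx": "mtx-triplet"}.get(path.suffix)
        if format is None:
            raise ValidationError(f"cannot infer format from {path.name!r}")
    if format == "mtx-triplet":
        rows = Path(str(path) + ".rows")
        cols = Path(str(path) + ".cols")
        for companion in (rows, cols):
            if not companion.exists():
                raise ValidationError(f"missing companion file {companion}")
        mat = scipy.io.mmread(str(path)).toarray()
        genes = rows.read_text().split()
        samples = cols.read_text().split()
        df = pd.DataFrame(mat, index=genes, columns=samples)
    elif format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0,
                             float_precision="round_trip")
        except (pd.errors.ParserError, ValueError) as exc:
            raise ValidationError(f"malformed expression file {path}: {exc}")
        non_numeric = df.columns[
            [not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]]
        if len(non_numeric):
            raise ValidationError(
                f"non-numeric expression columns: {list(non_numeric)[:5]}")
    else:
        raise ValidationError(f"unknown format {format!r}")
    if transpose:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, unit_tag=unit_tag)


def read_cell_table(prefix: str | Path) -> CellTable:
    """Read a :class:`CellTable` written by :meth:`CellTable.write`."""
    prefix = Path(prefix)
    expr = read_expression(Path(str(prefix) + ".mtx"), format="mtx-triplet")
    obs = pd.read_csv(str(prefix) + ".cells.tsv", sep="\t", index_col=0)
    obs.index = obs.index.astype(str)
    frame = expr.values.T  # cells × genes
    if list(frame.index) != list(obs.index):
        obs = obs.loc[frame.index]
    adata = ad.AnnData(X=frame.to_numpy(), obs=obs,
                       var=pd.DataFrame(index=frame.columns))
    adata.obs_names = frame.index
    return CellTable(adata)


def read_clinical(path: str | Path,
                  schema: Mapping[str, str] | None = None,
                  time_unit: str = "months",
                  sep: str = "\t") -> ClinicalTable:
    """Read a clinical table.

    ``schema`` maps the canonical column names (``id``, ``time``,
    ``event``, ``bor``, anything else passes through as a covariate) to the
    column names in the file.
    """
    schema = dict(schema or {})
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    rename = {}
    for canonical in ("id", "time", "event", "bor"):
        src = schema.get(canonical, canonical if canonical != "id" else "sample")
        if src in df.columns:
            rename[src] = canonical if canonical != "id" else "__id__"
    df = df.rename(columns=rename)
    if "__id__" not in df.columns:
        raise ValidationError(
            "clinical table needs an id column (default name 'sample')")
    for col in ("time", "event"):
        if col not in df.columns:
            raise ValidationError(f"clinical table missing column {col!r}")
    df = df.set_index("__id__")
    df.index = df.index.astype(str)
    df.index.name = "sample"
    return ClinicalTable(df, time_unit=time_unit)


# ---------------------------------------------------------------------------
# TPM
# ---------------------------------------------------------------------------

def raw_counts_to_tpm(counts: pd.DataFrame,
                      gene_lengths: Mapping[str, float]) -> ExpressionMatrix:
    """Convert raw read counts (genes × samples) to TPM.

    Per sample: rate = count / gene length (bases); TPM = rate / Σrate × 1e6,
    so every non-degenerate column sums to one million.  An all-zero sample
    yields an all-zero column with a warning.
    """
    lengths = pd.Series({g: float(gene_lengths[g]) for g in counts.index})
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][:5]
        raise ValidationError(f"non-positive gene lengths: {list(bad)}")
    rate = counts.div(lengths, axis=0).astype(float)
    colsum = rate.sum(axis=0)
    zero = colsum == 0
    if zero.any():
        warnings.warn(f"all-zero samples: {list(counts.columns[zero])}",
                      stacklevel=2)
        colsum = colsum.replace(0, np.nan)
    tpm = rate.div(colsum, axis=1) * 1e6
    tpm = tpm.fillna(0.0)
    return ExpressionMatrix(tpm, unit_tag="TPM")
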