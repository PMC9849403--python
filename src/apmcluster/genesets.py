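"""Canonical gene lists and constants of the APM clustering model.

The antigen-presenting-machinery (APM) signature is assembled from a fixed
base model of MHC class I/II genes plus a forward-selected combination of
additional APM features.  The lists below are the published defaults; every
pipeline stage accepts user-supplied lists instead.
"""

from __future__ import annotations

#: Base model: classical and non-classical HLA class I genes, HLA class II
#: genes, and the class I/II transactivators.
BASE_GENES: tuple[str, ...] = (
    "HLA-A", "HLA-B", "HLA-C", "HLA-E", "HLA-G", "HLA-F",
    "HLA-DRA", "HLA-DRB1", "HLA-DQA1", "HLA-DQB1", "HLA-DQA2", "HLA-DQB2",
    "HLA-DPA1", "HLA-DPB1",
    "NLRC5", "CIITA",
)

#: Additional APM features entering the powerset forward selection:
#: immunoproteasome subunits/activators, B2M, non-classical class II
#: paralogues, class II chaperones, and peptide loading/transport genes.
ADDITIONAL_CANDIDATES: tuple[str, ...] = (
    "PSME1", "PSME2", "PSMB8", "PSMB9", "PSMB10",
    "B2M",
    "HLA-DRB5", "HLA-DRB6",
    "HLA-DMA", "HLA-DMB", "HLA-DOA", "HLA-DOB",
    "ERAP1", "TAPBP", "TAP1", "TAP2",
)

#: The winning combination selected on the discovery cohorts; together with
#: the base model it forms the 23-gene APM signature.
SELECTED_ADDITIONAL: tuple[str, ...] = (
    "PSME1", "TAPBP", "PSMB10", "TAP2", "HLA-DRB6", "HLA-DMA", "HLA-DOB",
)

#: MHC class I pathway genes whose bulk expression is corrected for tumor
#: purity (class II genes are expressed by immune cells and left uncorrected).
MHC_I_CORRECTION_GENES: tuple[str, ...] = (
    "B2M", "HLA-A", "HLA-B", "HLA-C", "HLA-E", "HLA-F", "HLA-G",
    "ERAP1", "NLRC5",
    "PSMB1", "PSMB2", "PSMB8", "PSMB9", "PSMB10",
    "TAP1", "TAP2", "TAPBP",
)

#: Seven-gene housekeeping signature used as a per-cohort normalizer.
HG7_GENES: tuple[str, ...] = (
    "ACTB", "GAPDH", "UBC", "HMBS", "TBP", "HPRT1", "RPL13A",
)

#: Cytolytic-activity score genes.
CYT_GENES: tuple[str, ...] = ("GZMA", "PRF1")


def is_mhc_class_ii(gene: str) -> bool:
    """Route a signature gene to the MHC class II compartment.

    Class II genes (``HLA-D*``) and their transactivator ``CIITA`` are
    presented by immune cells; everything else in the signature belongs to
    the class I pathway.  Used when building classifier features from
    compartment-specific single-cell pseudobulk.
    """
    return gene.upper().startswith("HLA-D") or gene.upper() == "CIITA"
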