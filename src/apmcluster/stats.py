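"""Survival and response statistics for APM clusters.

Kaplan–Meier curves, the k-group log-rank test, a multivariate Cox
proportional-hazards wrapper, durable-clinical-benefit (DCB/NCB) derivation
from RECIST best overall response, exact cluster–benefit association tests,
paired pre/on-treatment comparisons, the cytolytic (CYT) score, and
Spearman correlations with Benjamini–Hochberg adjustment.

The k-group log-rank statistic is computed directly in its
observed-minus-expected form (hypergeometric variance at tied event times)
so that per-group observed and expected event counts can be reported; it is
cross-checked against ``lifelines`` in the test suite.  Kaplan–Meier and
Cox fits delegate to ``lifelines`` (Efron tie handling).
"""

from __future__ import annotations


import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats
from lifelines import CoxPHFitter, KaplanMeierFitter
from statsmodels.stats.multitest import multipletests

from .io import ClinicalTable, ExpressionMatrix, ValidationError


@dataclass
class SurvivalTestResult:
    """k-group log-rank test result with per-group event accounting."""

    statistic: float
    df: int
    p_value: float
    groups: list
    n_per_group: np.ndarray
    observed: np.ndarray
    expected: np.ndarray

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"SurvivalTestResult(chi2={self.statistic:.4g}, "
                f"df={self.df}, p={self.p_value:.4g})")


@dataclass
class CoxResult:
    """Multivariate Cox fit: hazard ratios, Wald CIs, diagnostics."""

    summary: pd.DataFrame          # index: covariate; HR, CI bounds, p
    converged: bool
    log_likelihood: float
    fitter: CoxPHFitter = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

def km_curves(times, events, groups) -> dict:
    """Per-group Kaplan–Meier product-limit estimates and medians.

    Returns ``{group: {"timeline", "survival", "median", "n"}}``; the median
    is the first time the survival function drops to 0.5 or below and is
    NaN when never reached.
    """
    df = pd.DataFrame({"time": np.asarray(times, dtype=float),
                       "event": np.asarray(events, dtype=int),
                       "group": np.asarray(groups)})
    out = {}
    for g, sub in df.groupby("group", sort=True):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        sf = kmf.survival_function_.iloc[:, 0]
        out[g] = {
            "timeline": sf.index.to_numpy(),
            "survival": sf.to_numpy(),
            "median": float(kmf.median_survival_time_),
            "n": int(len(sub)),
        }
    return out


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def logrank_test(times, events, groups) -> SurvivalTestResult:
    """k-group log-rank test (chi-square with k−1 degrees of freedom).

    At each distinct event time the observed events per group are compared
    with the expectation under the null of a common hazard, with the
    multivariate hypergeometric covariance handling ties; the quadratic
    form over any k−1 groups gives the statistic.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    if e.sum() == 0:
        raise ValidationError("log-rank test undefined with zero events")
    labels, gidx = np.unique(g, return_inverse=True)
    k = len(labels)
    if k < 2:
        raise ValidationError("log-rank test needs at least two groups")
    event_times = np.unique(t[e == 1])
    observed = np.zeros(k)
    expected = np.zeros(k)
    var = np.zeros((k, k))
    for tau in event_times:
        at_risk = t >= tau
        n_j = np.bincount(gidx[at_risk], minlength=k).astype(float)
        n_tot = n_j.sum()
        dying = at_risk & (t == tau) & (e == 1)
        d_j = np.bincount(gidx[dying], minlength=k).astype(float)
        d_tot = d_j.sum()
        if n_tot == 0 or d_tot == 0:
            continue
        observed += d_j
        expected += d_tot * n_j / n_tot
        if n_tot > 1:
            frac = n_j / n_tot
            scale = d_tot * (n_tot - d_tot) / (n_tot - 1)
            var += scale * (np.diag(frac) - np.outer(frac, frac))
    z = (observed - expected)[:-1]
    v = var[:-1, :-1]
    try:
        stat = float(z @ np.linalg.solve(v, z))
    except np.linalg.LinAlgError:
        stat = float(z @ np.linalg.pinv(v) @ z)
    stat = max(stat, 0.0)
    df = k - 1
    p = float(scipy.stats.chi2.sf(stat, df))
    return SurvivalTestResult(
        statistic=stat, df=df, p_value=max(p, np.nextafter(0, 1)),
        groups=list(labels), n_per_group=np.bincount(gidx, minlength=k),
        observed=observed, expected=expected)


# ---------------------------------------------------------------------------
# Cox
# ---------------------------------------------------------------------------

CLUSTER_CODING = {"C1": 1, "C2": 2, "C3": 3, "C4": 4}


def encode_cluster_labels(labels: Sequence[str]) -> pd.Series:
    """Code cluster labels as the continuous covariate C1=1 … C4=4."""
    out = []
    for lab in labels:
        if lab not in CLUSTER_CODING:
            raise ValidationError(f"unknown cluster label {lab!r}")
        out.append(CLUSTER_CODING[lab])
    return pd.Series(out, index=getattr(labels, "index", None),
                     name="apm_cluster", dtype=float)


def cox_multivariate(clinical: ClinicalTable,
                     covariates: Sequence[str] | None = None,
                     extra: pd.DataFrame | None = None) -> CoxResult:
    """Multivariate Cox proportional-hazards fit (Efron tie handling).

    ``covariates`` names columns of the clinical table (and of ``extra``,
    e.g. the cluster coding from :func:`encode_cluster_labels`).
    Non-convergence is flagged on the result, never silent.
    """
    df = pd.DataFrame({"time": clinical.time, "event": clinical.event})
    pool = clinical.covariates()
    if extra is not None:
        pool = pool.join(extra, how="left") if not pool.empty else extra.copy()
    cols = list(covariates) if covariates is not None else list(pool.columns)
    for c in cols:
        if c not in pool.columns:
            raise ValidationError(f"unknown covariate {c!r}")
        if pool[c].nunique() <= 1:
            raise ValidationError(f"constant covariate {c!r}")
        df[c] = pd.to_numeric(pool[c])
    n_events = int(df["event"].sum())
    if n_events < len(cols) + 1:
        warnings.warn(f"only {n_events} events for {len(cols)} covariates",
                      stacklevel=2)
    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except Exception as exc:
            raise ValidationError(f"Cox fit failed: {exc}")
    summ = cph.summary
    table = pd.DataFrame({
        "HR": summ["exp(coef)"],
        "CI95_low": summ["exp(coef) lower 95%"],
        "CI95_high": summ["exp(coef) upper 95%"],
        "p": summ["p"],
        "coef": summ["coef"],
        "se": summ["se(coef)"],
    })
    return CoxResult(summary=table, converged=converged,
                     log_likelihood=float(cph.log_likelihood_), fitter=cph)


# ---------------------------------------------------------------------------
# clinical benefit
# ---------------------------------------------------------------------------

def derive_benefit(bor: str | None, pfs_months: float | None = None,
                   progressed: bool | None = None) -> str | None:
    """DCB/NCB from RECIST best overall response.

    PD → NCB and any other evaluable response (CR/PR, SD) → DCB.  Mixed
    (MR) or non-evaluable (NE) responses count as DCB only when the patient
    remained progression-free for at least six months, NCB otherwise.
    Returns None (label withheld) when the inputs cannot decide.
    """
    if bor == "PD":
        return "NCB"
    if bor in ("CRPR", "SD"):
        return "DCB"
    if bor in ("MR", "NE") or bor is None:
        if pfs_months is None:
            warnings.warn("benefit label withheld: follow-up unknown",
                          stacklevel=2)
            return None
        # progression at or after the 6-month mark still counts as durable
        return "DCB" if pfs_months >= 6 else "NCB"
    raise ValidationError(f"unknown best-overall-response {bor!r}")


def derive_benefit_table(clinical: ClinicalTable) -> pd.Series:
    """Vectorized :func:`derive_benefit` over a clinical table.

    Uses PFS time converted to months; the event indicator marks
    progression for the MR/NE six-month rule.
    """
    months = clinical.time_in_months()
    out = {}
    for sid in clinical.sample_ids:
        bor = clinical.bor.get(sid)
        out[sid] = derive_benefit(bor, float(months.loc[sid]),
                                  bool(clinical.event.loc[sid]))
    return pd.Series(out, name="benefit")


# ---------------------------------------------------------------------------
# exact association tests
# ---------------------------------------------------------------------------

def _exact_kx2_pvalue(table: np.ndarray) -> float:
    """Two-sided exact test on a k×2 table by enumeration.

    Enumerates all tables with the observed margins; the p-value is the
    total null (multivariate hypergeometric) probability of tables no more
    probable than the observed one.  Intended for small tables.
    """
    table = np.asarray(table, dtype=int)
    row_sums = table.sum(axis=1)
    col1 = int(table[:, 0].sum())
    n = int(table.sum())
    logfact = scipy.special.gammaln(np.arange(n + 2) + 1.0)
    # normalizing constant log C(n, col1)
    log_norm = logfact[n] - logfact[col1] - logfact[n - col1]

    obs_lp = sum(logfact[r] - logfact[k_i] - logfact[r - k_i]
                 for r, k_i in zip(row_sums, table[:, 0])) - log_norm
    total = 0.0

    def recurse(i: int, remaining: int, lp: float) -> None:
        nonlocal total
        if i == len(row_sums) - 1:
            r = int(row_sums[i])
            if 0 <= remaining <= r:
                lpt = lp + logfact[r] - logfact[remaining] \
                    - logfact[r - remaining] - log_norm
                if lpt <= obs_lp + 1e-7:
                    total += math.exp(lpt)
            return
        r = int(row_sums[i])
        for k_i in range(0, min(r, remaining) + 1):
            recurse(i + 1, remaining - k_i,
                    lp + logfact[r] - logfact[k_i] - logfact[r - k_i])

    recurse(0, col1, 0.0)
    return min(total, 1.0)


def cluster_benefit_association(labels: pd.Series,
                                benefit: pd.Series,
                                max_exact_n: int = 500) -> dict:
    """Cluster × benefit contingency analysis.

    Builds the k×2 (cluster × DCB/NCB) table, reports the omnibus exact
    p-value (Fisher's exact test for k = 2, enumeration otherwise), the
    per-cluster one-vs-rest two-sided Fisher p-values, and the %DCB within
    each cluster.  Tables with a grand total beyond ``max_exact_n`` fall
    back to the chi-square approximation with a warning.
    """
    merged = pd.DataFrame({"cluster": labels, "benefit": benefit}).dropna()
    if merged.empty:
        raise ValidationError("no samples with both cluster and benefit")
    tab = pd.crosstab(merged["cluster"], merged["benefit"])
    for col in ("DCB", "NCB"):
        if col not in tab.columns:
            tab[col] = 0
    tab = tab[["DCB", "NCB"]]
    if (tab.sum(axis=1) > 0).sum() < 2:
        raise ValidationError("need at least two non-empty clusters")
    arr = tab.to_numpy()
    if arr.shape[0] == 2:
        p_omnibus = float(scipy.stats.fisher_exact(arr)[1])
    elif arr.sum() <= max_exact_n:
        p_omnibus = _exact_kx2_pvalue(arr)
    else:
        warnings.warn("table too large for enumeration; "
                      "chi-square approximation used", stacklevel=2)
        p_omnibus = float(scipy.stats.chi2_contingency(arr)[1])
    pairwise = {}
    total = arr.sum(axis=0)
    for i, cluster in enumerate(tab.index):
        rest = total - arr[i]
        two_by_two = np.array([arr[i], rest])
        pairwise[cluster] = float(scipy.stats.fisher_exact(two_by_two)[1])
    pct_dcb = (tab["DCB"] / tab.sum(axis=1) * 100).round(10)
    return {"table": tab, "p_omnibus": p_omnibus,
            "p_pairwise": pairwise, "pct_dcb": pct_dcb}


# ---------------------------------------------------------------------------
# paired comparisons, CYT, correlations
# ---------------------------------------------------------------------------

def group_score(expr: ExpressionMatrix, genes: Sequence[str]) -> pd.Series:
    """Per-sample mean log2(TPM+1) over a gene group."""
    sub = expr.subset_genes(list(genes))
    return np.log2(sub.values + 1.0).mean(axis=0)


def paired_group_comparison(pre_expr: ExpressionMatrix,
                            on_expr: ExpressionMatrix,
                            matched_ids: Sequence[tuple[str, str]],
                            genes: Sequence[str],
                            zero_method: str = "wilcox") -> dict:
    """Paired pre- vs on-treatment comparison of a gene-group score.

    The score is the mean log2(TPM+1) over ``genes``; matched pairs are
    compared with the two-sided Wilcoxon signed-rank test (exact null for
    n ≤ 25 non-zero differences, normal approximation beyond).  Zero
    differences are dropped by default (``zero_method="wilcox"``;
    ``"pratt"`` keeps them in the ranking).  All-zero differences are
    reported as no change rather than a p-value.
    """
    if not matched_ids:
        raise ValidationError("no matched pre/on pairs")
    pre = group_score(pre_expr, genes)
    on = group_score(on_expr, genes)
    pre_v = np.array([pre[a] for a, _ in matched_ids])
    on_v = np.array([on[b] for _, b in matched_ids])
    diff = on_v - pre_v
    nonzero = diff != 0
    if not nonzero.any():
        return {"n_pairs": len(diff), "statistic": np.nan, "p_value": np.nan,
                "median_diff": 0.0, "no_change": True}
    mode = "exact" if nonzero.sum() <= 25 and zero_method == "wilcox" \
        else "approx"
    stat, p = scipy.stats.wilcoxon(on_v, pre_v, zero_method=zero_method,
                                   mode=mode)
    return {"n_pairs": len(diff), "statistic": float(stat),
            "p_value": float(p), "median_diff": float(np.median(diff)),
            "no_change": False}


def cyt_score(expr: ExpressionMatrix) -> pd.Series:
    """Cytolytic score: log2 of the average TPM of GZMA and PRF1, plus one."""
    from .genesets import CYT_GENES
    missing = [g for g in CYT_GENES if g not in expr.values.index]
    if missing:
        raise ValidationError(f"CYT genes missing: {missing}")
    mean = expr.values.loc[list(CYT_GENES)].mean(axis=0)
    score = np.log2(mean + 1.0)
    score.name = "CYT"
    return score


def spearman_with_bh(x: Mapping[str, Sequence[float]],
                     y: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Per-group Spearman correlation with BH adjustment across groups.

    ``x`` and ``y`` map group name → paired observations (≥3 pairs each).
    Constant inputs yield NaN rho with a flag and are excluded from the
    adjustment.
    """
    rows = []
    for group in x:
        xv = np.asarray(x[group], dtype=float)
        yv = np.asarray(y[group], dtype=float)
        if len(xv) != len(yv) or len(xv) < 3:
            raise ValidationError(
                f"group {group!r} needs >=3 paired observations")
        if np.all(xv == xv[0]) or np.all(yv == yv[0]):
            rows.append((group, np.nan, np.nan, True))
            continue
        rho, p = scipy.stats.spearmanr(xv, yv)
        rows.append((group, float(rho), float(p), False))
    df = pd.DataFrame(rows, columns=["group", "rho", "p", "degenerate"])
    df = df.set_index("group")
    ok = ~df["degenerate"]
    df["p_bh"] = np.nan
    if ok.any():
        df.loc[ok, "p_bh"] = multipletests(df.loc[ok, "p"], method="fdr_bh")[1]
    return df
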