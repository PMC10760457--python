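"""Expression contrasts, CV across genotype lines, and structure models.

Covers the downstream gene-level questions: do structured genes sit at
different expression levels than unstructured genes (Welch t-test on
log(TPM + 1), plus a label-permutation test with optional equal-size
down-sampling of the larger group); how does expression relate to the
minMFE stability metric within each group; and is cross-genotype
expression variability (CV over the 26-line panel) coupled to smRNA
density and structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .seqs import InputError


@dataclass(frozen=True)
class CVRecord:
    gene_id: str
    mean_expression: float
    cv: float
    n_samples: int
    valid: bool


def expression_cv(values, gene_id: str = "") -> CVRecord:
    """Coefficient of variation: sample (n-1) SD over mean across lines.

    Genes with zero mean are flagged invalid (CV undefined), not dropped
    silently.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InputError("CV needs at least 2 samples")
    mean = float(arr.mean())
    if mean == 0:
        return CVRecord(gene_id, 0.0, float("nan"), arr.size, False)
    sd = float(arr.std(ddof=1))
    return CVRecord(gene_id, mean, sd / mean, arr.size, True)


def cv_frame(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene CV over a genes x samples expression matrix."""
    recs = [expression_cv(row.to_numpy(), gene_id=str(g))
            for g, row in matrix.iterrows()]
    return pd.DataFrame(
        [(r.gene_id, r.mean_expression, r.cv, r.n_samples, r.valid)
         for r in recs],
        columns=["gene_id", "mean_expression", "cv", "n_samples", "valid"],
    ).set_index("gene_id")


def compare_structured_expression(
    expression,
    structured,
    n_perm: int = 10000,
    seed: int = 0,
    downsample: bool = True,
):
    """Structured vs unstructured expression contrast.

    Welch t-test on log(expression + 1) plus a permutation test of the
    group-mean difference under label shuffles; when ``downsample`` is
    set the larger group is randomly down-sampled to the smaller group's
    size first (removing group-size artefacts from the contrast).

    Returns a dict with group means (log scale), t-test p, permutation p,
    and the observed difference (structured minus unstructured).
    """
    x = np.log1p(np.asarray(expression, dtype=float))
    lab = np.asarray(structured, dtype=bool)
    if lab.all() or (~lab).all():
        raise InputError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    a, b = x[lab], x[~lab]
    if downsample and len(a) != len(b):
        if len(a) > len(b):
            a = rng.choice(a, size=len(b), replace=False)
        else:
            b = rng.choice(b, size=len(a), replace=False)
    t_p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    pool = np.concatenate([a, b])
    na = len(a)
    obs = a.mean() - b.mean()
    count = 0
    for _ in range(n_perm):
        rng.shuffle(pool)
        diff = pool[:na].mean() - pool[na:].mean()
        if abs(diff) >= abs(obs) - 1e-15:
            count += 1
    perm_p = (count + 1) / (n_perm + 1)
    return {
        "mean_structured": float(a.mean()),
        "mean_unstructured": float(b.mean()),
        "difference": float(obs),
        "t_p": t_p,
        "perm_p": float(perm_p),
        "n_structured": int(lab.sum()),
        "n_unstructured": int((~lab).sum()),
    }


def _ols(y: np.ndarray, x: np.ndarray):
    import statsmodels.api as sm

    if len(x) < 3:
        raise InputError("need at least 3 observations")
    if np.all(x == x[0]):
        raise InputError("degenerate (constant) predictor")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return float(fit.params[1]), float(fit.rsquared), float(fit.pvalues[1])


def fit_expression_mfe_model(expression, min_mfe, group=None):
    """Per-group OLS of log(expression + 1) on minMFE.

    With ``group`` labels (e.g. structured / unstructured) one fit per
    group is returned, keyed by label, plus an ``opposing_slopes``
    diagnostic when exactly two groups are present.
    """
    y = np.log1p(np.asarray(expression, dtype=float))
    x = np.asarray(min_mfe, dtype=float)
    if group is None:
        slope, r2, p = _ols(y, x)
        return {"all": {"slope": slope, "r_squared": r2, "p": p}}
    group = np.asarray(group)
    out = {}
    for g in pd.unique(group):
        m = group == g
        slope, r2, p = _ols(y[m], x[m])
        out[g] = {"slope": slope, "r_squared": r2, "p": p}
    labels = list(out)
    if len(labels) == 2:
        out["opposing_slopes"] = (
            out[labels[0]]["slope"] * out[labels[1]]["slope"] < 0)
    return out


def fit_cv_models(cv, smrna_density=None, min_mfe=None, b73_expression=None):
    """The three CV regressions, each (slope, R^2, p).

    cv ~ smRNA density, cv ~ minMFE, and log(B73 expression + 1) ~ cv.
    Genes with invalid (NaN) CV are excluded pairwise.
    """
    cv = np.asarray(cv, dtype=float)
    out = {}
    if smrna_density is not None:
        d = np.asarray(smrna_density, dtype=float)
        ok = np.isfinite(cv) & np.isfinite(d)
        if ok.sum() < 3:
            raise InputError("fewer than 3 valid genes")
        s, r2, p = _ols(cv[ok], d[ok])
        out["cv_vs_density"] = {"slope": s, "r_squared": r2, "p": p}
    if min_mfe is not None:
        m = np.asarray(min_mfe, dtype=float)
        ok = np.isfinite(cv) & np.isfinite(m)
        if ok.sum() < 3:
            raise InputError("fewer than 3 valid genes")
        s, r2, p = _ols(cv[ok], m[ok])
        out["cv_vs_minmfe"] = {"slope": s, "r_squared": r2, "p": p}
    if b73_expression is not None:
        e = np.log1p(np.asarray(b73_expression, dtype=float))
        ok = np.isfinite(cv) & np.isfinite(e)
        if ok.sum() < 3:
            raise InputError("fewer than 3 valid genes")
        s, r2, p = _ols(e[ok], cv[ok])
        out["expression_vs_cv"] = {"slope": s, "r_squared": r2, "p": p}
    return out


def quartile_smrna_summary(min_mfe, smrna_counts) -> pd.DataFrame:
    """Mean smRNA count per minMFE quartile (quartile 1 = lowest minMFE).

    Ties are broken by stable input order so quartiles are equal-sized (to
    within one gene).
    """
    m = np.asarray(min_mfe, dtype=float)
    if m.size < 4:
        raise InputError("need at least 4 genes for quartiles")
    counts = np.asarray(smrna_counts, dtype=float)
    order = np.argsort(m, kind="stable")
    qsize = np.full(4, m.size // 4)
    qsize[: m.size % 4] += 1
    rows = []
    idx = 0
    for q in range(4):
        sel = order[idx: idx + qsize[q]]
        idx += qsize[q]
        rows.append((q + 1, len(sel), float(m[sel].mean()),
                     float(counts[sel].mean())))
    return pd.DataFrame(rows, columns=["quartile", "n_genes",
                                       "mean_min_mfe", "mean_smrna_count"])
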