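"""Differential expression for the two data branches.

miRNA counts: median-of-ratios size factors, then a negative-binomial
Wald test per feature for each timepoint contrast (T2..T6 vs T1).
Dispersion is estimated per feature by the method of moments on
normalized counts and shrunk toward a mean-dispersion trend fitted
across features (alpha(mu) = a0 + a1/mu), a documented simplification
of the shrinkage estimators used by count-based DE packages. Log2 fold
changes use group means of normalized counts with a 0.5 pseudocount.

Microarray log2 intensities: per-gene Welch two-sample t-test per
contrast, log2FC = mean(B) - mean(A).

Both branches use Benjamini-Hochberg adjustment within each contrast
and the study's significance filters: padj <= 0.05, |log2FC| >= 1 and
baseMean >= 10 for miRNAs; p <= 0.05 and |log2FC| >= 0.8 for mRNAs
(all bounds inclusive).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

CONTRASTS = ("T2", "T3", "T4", "T5", "T6")
BASELINE = "T1"


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, geometric mean rescaled to 1.

    Only features with strictly positive counts in every sample enter
    the geometric reference (the standard median-of-ratios rule).
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature has all-positive counts; median-of-ratios undefined "
            "(consider a pseudo-reference fallback)"
        )
    logs = np.log(mat[positive])
    log_geomean = logs.mean(axis=1)
    ratios = logs - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    factors /= np.exp(np.log(factors).mean())
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _fit_dispersion_trend(base_mean: np.ndarray, alpha_mom: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a0 + a1/mu over features with usable estimates."""
    use = (base_mean > 0) & (alpha_mom > 0)
    if use.sum() < 10:
        fallback = float(np.median(alpha_mom[alpha_mom > 0])) if (alpha_mom > 0).any() else 0.01
        return np.full_like(base_mean, max(fallback, 1e-8))
    X = np.column_stack([np.ones(use.sum()), 1.0 / base_mean[use]])
    coef, *_ = np.linalg.lstsq(X, alpha_mom[use], rcond=None)
    a0, a1 = max(coef[0], 0.0), max(coef[1], 0.0)
    trend = a0 + a1 / np.maximum(base_mean, 1e-8)
    return np.maximum(trend, 1e-8)


def nb_wald_test(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    factors: pd.Series,
    pseudocount: float = 0.5,
    moment_weight: float = 0.25,
) -> pd.DataFrame:
    """Per-feature NB Wald test of group B vs group A.

    Returns a frame with baseMean (mean normalized count over both
    groups), log2FC, SE and two-sided normal p. All-zero features get
    log2FC 0 and p 1, flagged in the ``all_zero`` column.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 samples per group")
    cols = list(group_a) + list(group_b)
    norm = counts[cols].to_numpy(dtype=float) / factors[cols].to_numpy()
    na, nb = len(group_a), len(group_b)
    A, B = norm[:, :na], norm[:, na:]
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    base_mean = norm.mean(axis=1)

    # pooled within-group moments for the dispersion estimate
    var_pooled = (A.var(axis=1, ddof=1) * (na - 1) + B.var(axis=1, ddof=1) * (nb - 1)) / (na + nb - 2)
    mean_pooled = np.maximum(base_mean, 1e-8)
    alpha_mom = np.maximum(0.0, (var_pooled - mean_pooled) / mean_pooled**2)
    alpha_trend = _fit_dispersion_trend(base_mean, alpha_mom)
    alpha = moment_weight * alpha_mom + (1.0 - moment_weight) * alpha_trend

    log2fc = np.log2(mean_b + pseudocount) - np.log2(mean_a + pseudocount)
    # delta method on log2 of an NB group mean: var(log2 mean) ~ (1/mu + alpha)/(n ln2^2)
    ln2sq = np.log(2.0) ** 2
    var_log2 = (1.0 / np.maximum(mean_a, pseudocount) + alpha) / (na * ln2sq) + (
        1.0 / np.maximum(mean_b, pseudocount) + alpha
    ) / (nb * ln2sq)
    se = np.sqrt(var_log2)
    z = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * sps.norm.sf(np.abs(z))

    all_zero = (counts[cols].to_numpy() == 0).all(axis=1)
    log2fc[all_zero] = 0.0
    p[all_zero] = 1.0
    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": log2fc,
            "SE": se,
            "p": np.clip(p, 0.0, 1.0),
            "all_zero": all_zero,
        },
        index=counts.index,
    )


def ttest_expr(expr: pd.DataFrame, group_a: list[str], group_b: list[str]) -> pd.DataFrame:
    """Welch t-test per gene on log2 intensities; log2FC = mean(B) - mean(A)."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 samples per group")
    A = expr[list(group_a)].to_numpy(dtype=float)
    B = expr[list(group_b)].to_numpy(dtype=float)
    log2fc = B.mean(axis=1) - A.mean(axis=1)
    t, p = sps.ttest_ind(B, A, axis=1, equal_var=False)
    # degenerate: zero variance in both groups
    degenerate = ~np.isfinite(p)
    p = np.where(degenerate, np.where(np.isclose(log2fc, 0.0), 1.0, 0.0), p)
    return pd.DataFrame({"log2FC": log2fc, "t": t, "p": p}, index=expr.index)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if np.isnan(p).any():
        raise ValueError("NaN p-value in input")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _groups_by_timepoint(samples: pd.DataFrame) -> dict[str, list[str]]:
    """samples: index sample id, column 'timepoint' with labels T1..T6."""
    return {tp: list(sub.index) for tp, sub in samples.groupby("timepoint")}


def de_mirna(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
    min_base_mean: float = 10.0,
) -> pd.DataFrame:
    """miRNA-branch DE over all contrasts vs T1, with the study filters."""
    factors = size_factors(counts)
    groups = _groups_by_timepoint(samples)
    norm = counts / factors
    out = pd.DataFrame(index=counts.index)
    out["baseMean"] = norm.mean(axis=1)
    for tp in CONTRASTS:
        res = nb_wald_test(counts, groups[BASELINE], groups[tp], factors)
        out[f"log2FC_{tp}"] = res["log2FC"]
        out[f"p_{tp}"] = res["p"]
        out[f"padj_{tp}"] = bh_adjust(res["p"].to_numpy())
    return apply_de_filters(out, "mirna", alpha=alpha, lfc_threshold=lfc_threshold, min_base_mean=min_base_mean)


def de_mrna(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    alpha: float = 0.05,
    lfc_threshold: float = 0.8,
) -> pd.DataFrame:
    """mRNA-branch DE (Welch t-test per contrast vs T1) with study filters."""
    groups = _groups_by_timepoint(samples)
    out = pd.DataFrame(index=expr.index)
    for tp in CONTRASTS:
        res = ttest_expr(expr, groups[BASELINE], groups[tp])
        out[f"log2FC_{tp}"] = res["log2FC"]
        out[f"p_{tp}"] = res["p"]
        out[f"padj_{tp}"] = bh_adjust(res["p"].to_numpy())
    return apply_de_filters(out, "mrna", alpha=alpha, lfc_threshold=lfc_threshold)


def apply_de_filters(
    results: pd.DataFrame,
    branch: str,
    alpha: float = 0.05,
    lfc_threshold: float | None = None,
    min_base_mean: float = 10.0,
) -> pd.DataFrame:
    """Attach per-contrast de_flag columns and a de_any column.

    miRNA branch: padj <= alpha AND |log2FC| >= 1 AND baseMean >= 10.
    mRNA branch: p <= alpha AND |log2FC| >= 0.8. Bounds inclusive.
    """
    out = results.copy()
    if branch == "mirna":
        lfc = 1.0 if lfc_threshold is None else lfc_threshold
        base_ok = out["baseMean"] >= min_base_mean
        for tp in CONTRASTS:
            out[f"de_{tp}"] = (out[f"padj_{tp}"] <= alpha) & (out[f"log2FC_{tp}"].abs() >= lfc) & base_ok
    elif branch == "mrna":
        lfc = 0.8 if lfc_threshold is None else lfc_threshold
        for tp in CONTRASTS:
            out[f"de_{tp}"] = (out[f"p_{tp}"] <= alpha) & (out[f"log2FC_{tp}"].abs() >= lfc)
    else:
        raise ValueError(f"unknown branch {branch!r} (expected 'mirna' or 'mrna')")
    out["de_any"] = out[[f"de_{tp}" for tp in CONTRASTS]].any(axis=1)
    return out


def fold_change_profiles(de_table: pd.DataFrame, features: list[str] | None = None) -> pd.DataFrame:
    """T2..T6 log2FC profile matrix for the given (default: DE) features."""
    if features is None:
        features = list(de_table.index[de_table["de_any"]])
    cols = [f"log2FC_{tp}" for tp in CONTRASTS]
    prof = de_table.loc[features, cols].copy()
    prof.columns = list(CONTRASTS)
    return prof
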