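"""Annotate DE genes against miRNA cluster-mean profiles.

A gene's T2..T6 log2 fold-change profile is correlated with each
cluster-mean miRNA profile; |r| beyond 0.67 (strict) annotates the gene
as positively or negatively correlated with that cluster. Genes
negative to at least one cluster form the candidate target background;
each is assigned to the cluster with the largest |r| for reporting.
Pearson r is the default (Spearman available), computed on fold-change
profiles. The expressed-miRNA filter (raw count > 10 in at least 2/3 of
samples) gates which miRNAs enter clustering upstream.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import rankdata


def expressed_filter(counts: pd.DataFrame, min_count: int = 10, min_fraction: float = 2 / 3) -> list[str]:
    """Features with raw count > min_count (strict) in >= ceil(frac * n) samples."""
    n = counts.shape[1]
    need = math.ceil(min_fraction * n)
    ok = (counts.to_numpy() > min_count).sum(axis=1) >= need
    return list(counts.index[ok])


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "spearman":
        x, y = rankdata(x), rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def gene_cluster_correlation(
    gene_profiles: pd.DataFrame,
    cluster_means: pd.DataFrame,
    method: str = "pearson",
) -> pd.DataFrame:
    """Per-gene, per-cluster correlation matrix (genes x clusters).

    Zero-variance gene profiles yield NaN (direction 'none' downstream).
    """
    if gene_profiles.shape[1] != cluster_means.shape[1]:
        raise ValueError("gene and cluster profiles must cover the same timepoints")
    G = gene_profiles.to_numpy(dtype=float)
    out = {}
    for cluster_id, mean_profile in cluster_means.iterrows():
        m = mean_profile.to_numpy(dtype=float)
        out[cluster_id] = [_corr(g, m, method) for g in G]
    return pd.DataFrame(out, index=gene_profiles.index)


def annotate_directions(r: pd.DataFrame, threshold: float = 0.67) -> pd.DataFrame:
    """Strict-threshold direction per cluster plus best-cluster assignment.

    Columns: one direction column per cluster ('negative'/'positive'/
    'none'), ``best_cluster`` (argmax |r|, NaN-safe), ``best_r`` and
    ``any_negative``. r exactly at +-threshold is 'none' (strict).
    """
    vals = r.to_numpy(dtype=float)
    directions = np.full(vals.shape, "none", dtype=object)
    with np.errstate(invalid="ignore"):
        directions[vals > threshold] = "positive"
        directions[vals < -threshold] = "negative"
    out = pd.DataFrame(directions, index=r.index, columns=[f"dir_{c}" for c in r.columns])
    abs_r = np.abs(np.nan_to_num(vals, nan=-1.0))
    best_idx = abs_r.argmax(axis=1)
    out["best_cluster"] = [str(r.columns[i]) for i in best_idx]
    out["best_r"] = vals[np.arange(len(r)), best_idx]
    out["any_negative"] = (directions == "negative").any(axis=1)
    for c in r.columns:
        out[f"r_{c}"] = r[c]
    return out


def negative_gene_partition(annotations: pd.DataFrame) -> dict[object, list[str]]:
    """Genes negative to >= 1 cluster, partitioned by their best cluster.

    A gene negative to several clusters appears once, under the cluster
    with the largest |r| (the disjoint group-A/group-B style report).
    """
    clusters = [c[4:] for c in annotations.columns if isinstance(c, str) and c.startswith("dir_")]
    neg = annotations[annotations["any_negative"]]
    partition: dict[str, list[str]] = {}
    for gene, row in neg.iterrows():
        negative = [c for c in clusters if row[f"dir_{c}"] == "negative"]
        chosen = max(negative, key=lambda c: abs(row[f"r_{c}"]))
        partition.setdefault(chosen, []).append(gene)
    return partition
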