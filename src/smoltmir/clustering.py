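"""Fold-change profile clustering for DE miRNAs.

Profiles are the 5-vectors of log2 fold changes (T2..T6, each vs T1).
Two published procedures meet here: hierarchical clustering with
Spearman-correlation distance and complete linkage supplies the tree
and heatmap ordering, while the gap statistic on k-means (uniform
reference over per-dimension ranges, firstSEmax rule) chooses the
number of clusters k. The tree is cut at that k for the final labels;
k-means labels at the same k are reported alongside for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list
from scipy.stats import rankdata
from sklearn.cluster import KMeans


def spearman_distance(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise d = 1 - rho_s (rank correlation, average ranks on ties)."""
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 profiles")
    X = profiles.to_numpy(dtype=float)
    ranks = np.apply_along_axis(rankdata, 1, X)
    sd = ranks.std(axis=1)
    if (sd == 0).any():
        flat = list(profiles.index[sd == 0])
        raise ValueError(f"constant profile(s) have undefined rank correlation: {flat}")
    rho = np.corrcoef(ranks)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


def complete_linkage_cluster(dist: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Agglomerative complete linkage; returns a scipy-format linkage matrix.

    Merges the closest pair of clusters under the maximum inter-cluster
    distance; ties break deterministically on the smallest (i, j)
    cluster-index pair (scipy numbering: originals 0..n-1, then n+step).
    """
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    # active cluster id -> (member set, distance row key)
    dist_between: dict[tuple[int, int], float] = {}
    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            dist_between[(i, j)] = D[i, j]
    Z = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = None
        for a_idx in range(len(active)):
            for b_idx in range(a_idx + 1, len(active)):
                i, j = active[a_idx], active[b_idx]
                d = dist_between[(min(i, j), max(i, j))]
                key = (d, min(i, j), max(i, j))
                if best is None or key < best:
                    best = key
        d, i, j = best
        Z[step] = [i, j, d, sizes[i] + sizes[j]]
        for other in active:
            if other in (i, j):
                continue
            di = dist_between[(min(i, other), max(i, other))]
            dj = dist_between[(min(j, other), max(j, other))]
            dist_between[(min(other, next_id), max(other, next_id))] = max(di, dj)
        sizes[next_id] = sizes[i] + sizes[j]
        active = [c for c in active if c not in (i, j)] + [next_id]
        next_id += 1
    return Z


def gap_statistic_k(
    profiles: pd.DataFrame,
    k_max: int = 6,
    B: int = 50,
    rng_seed: int = 0,
    n_restarts: int = 25,
) -> tuple[int, pd.DataFrame]:
    """Choose k by the gap statistic on k-means.

    Gap(k) = mean_b log(W*_kb) - log(W_k), with W_k the within-cluster
    sum of squared distances from the best of ``n_restarts`` k-means
    runs and reference sets drawn uniformly over each dimension's
    observed range. Selection: smallest k with
    Gap(k) >= Gap(k+1) - s_{k+1} (firstSEmax).
    """
    X = profiles.to_numpy(dtype=float)
    n = X.shape[0]
    if not 1 <= k_max < n:
        raise ValueError("require 1 <= k_max < number of profiles")
    if B < 10:
        raise ValueError("B >= 10 required for a stable reference")
    rng = np.random.default_rng(rng_seed)
    lo, hi = X.min(axis=0), X.max(axis=0)

    def inertia(data: np.ndarray, k: int) -> float:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=int(rng.integers(2**31 - 1)))
        km.fit(data)
        return max(km.inertia_, 1e-12)

    refs = [rng.uniform(lo, hi, size=X.shape) for _ in range(B)]
    rows = []
    for k in range(1, k_max + 1):
        log_w = np.log(inertia(X, k))
        log_w_ref = np.array([np.log(inertia(ref, k)) for ref in refs])
        gap = log_w_ref.mean() - log_w
        s = log_w_ref.std(ddof=0) * np.sqrt(1.0 + 1.0 / B)
        rows.append({"k": k, "log_W": log_w, "gap": gap, "s": s})
    curve = pd.DataFrame(rows).set_index("k")
    chosen = k_max
    for k in range(1, k_max):
        if curve.loc[k, "gap"] >= curve.loc[k + 1, "gap"] - curve.loc[k + 1, "s"]:
            chosen = k
            break
    return chosen, curve


@dataclass
class ClusterSet:
    """Cut tree: labels in 1..k, per-cluster mean profiles, leaf order."""

    labels: pd.Series
    k: int
    means: pd.DataFrame
    leaf_order: list[str]
    linkage: np.ndarray | None = None


def cut_and_summarize(Z: np.ndarray, profiles: pd.DataFrame, k: int) -> ClusterSet:
    """Cut the dendrogram into k groups and summarize.

    Labels are renumbered 1..k in order of first appearance along the
    dendrogram leaf order, so numbering is deterministic.
    """
    n = profiles.shape[0]
    if not 1 <= k <= n:
        raise ValueError("require 1 <= k <= n")
    raw = fcluster(Z, t=k, criterion="maxclust")
    order = leaves_list(Z.astype(np.float64))
    relabel: dict[int, int] = {}
    for idx in order:
        relabel.setdefault(raw[idx], len(relabel) + 1)
    labels = pd.Series([relabel[c] for c in raw], index=profiles.index, name="cluster")
    means = profiles.groupby(labels).mean()
    means.index.name = "cluster"
    leaf_order = [profiles.index[i] for i in order]
    return ClusterSet(labels=labels, k=int(labels.max()), means=means, leaf_order=leaf_order)


def dendrogram_to_json(Z: np.ndarray, leaf_names: list[str]) -> dict:
    """Linkage matrix as a plain JSON-serializable dict."""
    return {
        "leaves": list(leaf_names),
        "merges": [
            {"left": int(a), "right": int(b), "height": float(h), "size": int(s)}
            for a, b, h, s in Z
        ],
    }


def kmeans_labels(profiles: pd.DataFrame, k: int, rng_seed: int = 0, n_restarts: int = 25) -> pd.Series:
    """Companion k-means labels at the chosen k (Euclidean geometry)."""
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=rng_seed).fit(profiles.to_numpy(dtype=float))
    return pd.Series(km.labels_ + 1, index=profiles.index, name="kmeans_cluster")


def cluster_profiles(
    profiles: pd.DataFrame,
    k_max: int = 6,
    B: int = 50,
    rng_seed: int = 0,
) -> tuple[ClusterSet, pd.DataFrame, pd.Series]:
    """Distance -> tree -> gap-chosen k -> cut; returns set, gap curve, k-means labels."""
    dist = spearman_distance(profiles)
    Z = complete_linkage_cluster(dist)
    k, curve = gap_statistic_k(profiles, k_max=min(k_max, len(profiles) - 1), B=B, rng_seed=rng_seed)
    cs = cut_and_summarize(Z, profiles, k)
    cs.linkage = Z
    km = kmeans_labels(profiles, k, rng_seed=rng_seed)
    return cs, curve, km


def classify_archetype(mean_profile) -> str:
    """Shape label for a cluster-mean trajectory over T2..T6.

    sustained_decrease: all entries <= 0 with the minimum at T6;
    transient_t5_dip: minimum at T5; sustained_increase: all >= 0.
    """
    v = np.asarray(mean_profile, dtype=float)
    if (v <= 0).all() and v.argmin() == len(v) - 1:
        return "sustained_decrease"
    if v.argmin() == len(v) - 2:
        return "transient_t5_dip"
    if (v >= 0).all():
        return "sustained_increase"
    return "other"


def plot_heatmap(profiles: pd.DataFrame, clusters: ClusterSet, path: str) -> None:
    """Static heatmap with rows in dendrogram leaf order."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = profiles.loc[clusters.leaf_order]
    fig, ax = plt.subplots(figsize=(6, max(4, 0.15 * len(ordered))))
    vmax = np.abs(ordered.to_numpy()).max() or 1.0
    im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(ordered.shape[1]), ordered.columns)
    ax.set_yticks(range(len(ordered)), ordered.index, fontsize=5)
    for label, tick in zip(clusters.labels.loc[clusters.leaf_order], ax.get_yticklabels()):
        tick.set_color(["black", "red", "blue", "green", "purple"][(label - 1) % 5])
    fig.colorbar(im, ax=ax, label="log2 fold change vs T1")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
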