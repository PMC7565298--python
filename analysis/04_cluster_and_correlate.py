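#!/usr/bin/env python
"""Cluster DE miRNA fold-change profiles and correlate DE genes to them.

Profiles (log2FC at T2..T6 vs T1) of expressed DE miRNAs are clustered
with Spearman-distance complete linkage; the gap statistic on k-means
chooses k (expected: the three planted archetypes). DE gene profiles
are then annotated positively/negatively correlated to each cluster
mean at the +-0.67 threshold.
"""

from pathlib import Path

import pandas as pd

from smoltmir.clustering import classify_archetype, cluster_profiles, plot_heatmap
from smoltmir.correlate import annotate_directions, expressed_filter, gene_cluster_correlation
from smoltmir.diffexpr import fold_change_profiles

RUN_DIR = Path(__file__).resolve().parent.parent / "results" / "run"
SEED = 1


def main() -> None:
    counts = pd.read_csv(RUN_DIR / "mirna_counts.tsv", sep="\t", index_col=0)
    mirna_de = pd.read_csv(RUN_DIR / "de_mirna.tsv", sep="\t", index_col=0)
    mrna_de = pd.read_csv(RUN_DIR / "de_mrna.tsv", sep="\t", index_col=0)

    expressed = expressed_filter(counts)
    de_ids = [m for m in mirna_de.index[mirna_de["de_any"]] if m in expressed]
    profiles = fold_change_profiles(mirna_de, de_ids)
    cs, gap_curve, km = cluster_profiles(profiles, k_max=6, B=50, rng_seed=SEED)
    pd.DataFrame({"cluster": cs.labels, "kmeans_cluster": km}).to_csv(RUN_DIR / "mirna_clusters.tsv", sep="\t")
    cs.means.to_csv(RUN_DIR / "cluster_means.tsv", sep="\t")
    gap_curve.to_csv(RUN_DIR / "gap_curve.tsv", sep="\t")
    plot_heatmap(profiles, cs, str(RUN_DIR / "heatmap.png"))

    gene_profiles = fold_change_profiles(mrna_de)
    r = gene_cluster_correlation(gene_profiles, cs.means)
    annotations = annotate_directions(r)
    annotations.to_csv(RUN_DIR / "gene_correlations.tsv", sep="\t")

    shapes = {c: classify_archetype(cs.means.loc[c]) for c in cs.means.index}
    print(f"gap statistic chose k = {cs.k}; cluster shapes: {shapes}")
    print(f"{int(annotations['any_negative'].sum())} DE genes negatively correlated to >= 1 cluster")


if __name__ == "__main__":
    main()
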