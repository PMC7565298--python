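"""End-to-end orchestration and pair-table reporting.

Runs the full integrative analysis from a config: simulate (or ingest)
inputs -> quantify small-RNA reads -> differential expression on both
branches -> cluster DE miRNA fold-change profiles -> correlate DE gene
profiles with cluster means -> predict seed+MFE targets -> join into
the final table of negatively correlated predicted target pairs ->
overrepresentation analysis. Every intermediate is written as TSV and
the run is deterministic given the seed.
"""

from __future__ import annotations

import json
import warnings
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import classify_archetype, cluster_profiles, plot_heatmap
from .correlate import annotate_directions, expressed_filter, gene_cluster_correlation
from .diffexpr import CONTRASTS, de_mirna, de_mrna, fold_change_profiles, size_factors
from .enrich import AnnotationTable, filter_significant, fisher_enrich, hierarchical_rollup
from .quantify import MiRNAReference, quantify_samples
from .simulate import SimulationConfig, SyntheticDataset, config_from_dict, simulate_all, write_fastq_files
from .targets import DuplexHit, find_seed_sites, predict_targets


def load_fixture(name: str) -> pd.DataFrame:
    """Shipped transcriptions of the published summary tables."""
    with resources.files("smoltmir.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_table4_pairs() -> pd.DataFrame:
    """Published pair table: gene, miRNA, cluster, major-expressed flag."""
    df = load_fixture("table4_pairs.tsv")
    df["major_expressed"] = df["major_expressed"].astype(bool)
    return df


def load_cluster_profile_tables() -> pd.DataFrame:
    """Published per-miRNA log2FC profiles with cluster labels (all three)."""
    t2 = load_fixture("table2_cluster_I_II_profiles.tsv")
    t3 = load_fixture("table3_cluster_III_profiles.tsv")
    return pd.concat([t2, t3], ignore_index=True)


def flag_major_expressed(counts: pd.DataFrame, reference: MiRNAReference) -> pd.Series:
    """Within each miRNA family, flag the mature with highest mean normalized count.

    Ties flag every tied member; an all-zero family flags none (warns).
    """
    factors = size_factors(counts)
    means = (counts / factors).mean(axis=1)
    family = reference.family_of()
    flags = pd.Series(False, index=counts.index, name="major_expressed")
    fam_members: dict[str, list[str]] = {}
    for mid in counts.index:
        fam_members.setdefault(family.get(mid, mid), []).append(mid)
    for fam, members in fam_members.items():
        sub = means.loc[members]
        if sub.sum() <= 0:
            warnings.warn(f"family {fam} has zero total counts; no major-expressed member")
            continue
        flags.loc[sub.index[sub == sub.max()]] = True
    return flags


def build_pair_table(
    hits: list[DuplexHit],
    annotations: pd.DataFrame,
    mirna_clusters: pd.Series,
    major_flags: pd.Series,
) -> pd.DataFrame:
    """Join predictions with correlation directions and cluster labels.

    A (miRNA, gene) hit is retained when the gene is annotated
    negatively correlated with the miRNA's cluster; one row per pair,
    keeping the lowest-MFE site.
    """
    missing_m = sorted({h.mirna_id for h in hits} - set(mirna_clusters.index))
    missing_g = sorted({h.utr_id for h in hits} - set(annotations.index))
    if missing_m or missing_g:
        raise ValueError(
            f"id mismatch between stages: miRNAs without cluster labels {missing_m[:5]}, "
            f"genes without correlation annotation {missing_g[:5]}"
        )
    best: dict[tuple[str, str], DuplexHit] = {}
    for h in hits:
        key = (h.mirna_id, h.utr_id)
        if key not in best or h.mfe < best[key].mfe:
            best[key] = h
    rows = []
    for (mid, gene), h in sorted(best.items()):
        cluster = str(mirna_clusters.loc[mid])
        if annotations.loc[gene, f"dir_{cluster}"] != "negative":
            continue
        rows.append(
            {
                "gene": gene,
                "mirna": mid,
                "cluster": cluster,
                "direction": "negative",
                "major_expressed": bool(major_flags.get(mid, False)),
                "r": float(annotations.loc[gene, f"r_{cluster}"]),
                "seed_pos": h.seed_pos,
                "site_start": h.site_start,
                "site_end": h.site_end,
                "mfe": h.mfe,
            }
        )
    cols = ["gene", "mirna", "cluster", "direction", "major_expressed", "r", "seed_pos", "site_start", "site_end", "mfe"]
    return pd.DataFrame(rows, columns=cols)


def summarize_pair_table(pairs: pd.DataFrame) -> dict:
    """Degree summaries of the final (miRNA, target) table."""
    if pairs.empty:
        raise ValueError("empty pair table")
    genes = pairs["gene"].unique()
    per_mirna = pairs.groupby("mirna")["gene"].nunique().sort_values(ascending=False)
    per_gene = pairs.groupby("gene")["mirna"].nunique().sort_values(ascending=False)
    covered = pairs[pairs["major_expressed"]]["gene"].unique()
    per_cluster_genes = pairs.groupby("cluster")["gene"].nunique()
    per_cluster_mirnas = pairs.groupby("cluster")["mirna"].nunique()
    return {
        "n_target_genes": int(len(genes)),
        "n_targeting_mirnas": int(per_mirna.size),
        "per_mirna_degree": per_mirna.to_dict(),
        "per_gene_indegree": per_gene.to_dict(),
        "major_expressed_gene_fraction": float(len(covered) / len(genes)),
        "per_cluster_gene_counts": {str(k): int(v) for k, v in per_cluster_genes.items()},
        "per_cluster_mirna_counts": {str(k): int(v) for k, v in per_cluster_mirnas.items()},
    }


def table4_pair_table() -> pd.DataFrame:
    """The shipped published pair table in pair-table layout."""
    df = load_table4_pairs()
    out = df.rename(columns={})[["gene", "mirna", "cluster", "major_expressed"]].copy()
    out["direction"] = "negative"
    return out


def validate_pair_table(
    pairs: pd.DataFrame,
    mirna_seqs: dict[str, str],
    utrs: dict[str, str],
    annotations: pd.DataFrame,
    mfe_threshold: float = -18.0,
) -> bool:
    """Independent re-check: seed site present, MFE at threshold, direction negative."""
    for row in pairs.itertuples(index=False):
        if row.mfe > mfe_threshold:
            return False
        if row.seed_pos not in find_seed_sites(utrs[row.gene], mirna_seqs[row.mirna]):
            return False
        if annotations.loc[row.gene, f"dir_{row.cluster}"] != "negative":
            return False
    return True


# ---------------------------------------------------------------------------
# run directory plumbing


def _write_fasta(path: Path, records: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n{seq}\n")


def _read_fasta(path: Path) -> dict[str, str]:
    from Bio.SeqIO import parse

    return {rec.id: str(rec.seq) for rec in parse(str(path), "fasta")}


def _annotation_frame(annotation: AnnotationTable) -> pd.DataFrame:
    rows = []
    for gene, terms in sorted(annotation.gene_terms.items()):
        for term in sorted(terms):
            parent = sorted(annotation.parents.get(term, {""}))[0]
            rows.append(
                {"gene": gene, "term": term, "name": annotation.term_names.get(term, term), "parent": parent}
            )
    return pd.DataFrame(rows)


def run_pipeline(config: str | Path | dict, out_dir: str | Path | None = None) -> dict:
    """Execute every stage from a YAML config (or equivalent dict).

    Config keys: ``mode`` (synthetic), ``out_dir``, ``seed``,
    ``simulation`` (SimulationConfig overrides), ``clustering``
    (k_max, B), ``targets`` (mfe_threshold), ``thresholds``. Returns
    the summary dict (also written as summary.json).
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(config)
    out = Path(out_dir or cfg.get("out_dir", "smoltmir_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    mode = cfg.get("mode", "synthetic")
    if mode != "synthetic":
        raise NotImplementedError("real-data ingestion uses the stage CLI; run mode supports synthetic")

    sim_overrides = dict(cfg.get("simulation", {}))
    sim_overrides.setdefault("rng_seed", seed)
    sim_config = config_from_dict(sim_overrides)
    ds = simulate_all(sim_config)
    stage_write_inputs(ds, out)

    fastq_paths = {s: out / "fastq" / f"{s}.fastq" for s in ds.counts.columns}
    counts, stats = quantify_samples(fastq_paths, ds.reference)
    counts.to_csv(out / "mirna_counts.tsv", sep="\t")
    stats.to_csv(out / "mapping_stats.tsv", sep="\t")

    mirna_de = de_mirna(counts, ds.samples)
    mirna_de.to_csv(out / "de_mirna.tsv", sep="\t")
    mrna_de = de_mrna(ds.expr, ds.expr_samples)
    mrna_de.to_csv(out / "de_mrna.tsv", sep="\t")

    expressed = expressed_filter(counts)
    de_ids = [m for m in mirna_de.index[mirna_de["de_any"]] if m in expressed]
    profiles = fold_change_profiles(mirna_de, de_ids)
    clus_cfg = cfg.get("clustering", {})
    cs, gap_curve, km_labels = cluster_profiles(
        profiles,
        k_max=int(clus_cfg.get("k_max", 6)),
        B=int(clus_cfg.get("B", 50)),
        rng_seed=seed,
    )
    labels = pd.DataFrame({"cluster": cs.labels, "kmeans_cluster": km_labels})
    labels.to_csv(out / "mirna_clusters.tsv", sep="\t")
    cs.means.to_csv(out / "cluster_means.tsv", sep="\t")
    gap_curve.to_csv(out / "gap_curve.tsv", sep="\t")
    if cs.linkage is not None:
        from .clustering import dendrogram_to_json

        with open(out / "dendrogram.json", "w") as fh:
            json.dump(dendrogram_to_json(cs.linkage, list(profiles.index)), fh, indent=2)
    try:
        plot_heatmap(profiles, cs, str(out / "heatmap.png"))
    except Exception:  # plotting is best-effort, never fails a run
        pass

    de_genes = list(mrna_de.index[mrna_de["de_any"]])
    gene_profiles = fold_change_profiles(mrna_de, de_genes)
    r = gene_cluster_correlation(gene_profiles, cs.means)
    annotations = annotate_directions(r)
    annotations.to_csv(out / "gene_correlations.tsv", sep="\t")

    major = flag_major_expressed(counts, ds.reference)
    tgt_cfg = cfg.get("targets", {})
    mfe_threshold = float(tgt_cfg.get("mfe_threshold", sim_config.mfe_threshold))
    mirna_seqs = {m: s for m, s in ds.mirna_seqs.items() if m in de_ids}
    utrs = {g: ds.utrs[g] for g in de_genes if g in ds.utrs}
    hits = predict_targets(mirna_seqs, utrs, mfe_threshold=mfe_threshold) if mirna_seqs and utrs else []
    hits_frame = pd.DataFrame(
        [
            {
                "mirna": h.mirna_id,
                "gene": h.utr_id,
                "seed_pos": h.seed_pos,
                "site_start": h.site_start,
                "site_end": h.site_end,
                "mfe": h.mfe,
                "pairing": h.pairing,
            }
            for h in hits
        ]
    )
    hits_frame.to_csv(out / "duplex_hits.tsv", sep="\t", index=False)

    pair_table = build_pair_table(hits, annotations, cs.labels, major)
    pair_table.to_csv(out / "pair_table.tsv", sep="\t", index=False)

    study = set(pair_table["gene"])
    background = set(ds.annotation.gene_terms)
    enr = fisher_enrich(study, background, ds.annotation) if study else pd.DataFrame()
    if not enr.empty:
        enr.to_csv(out / "enrichment.tsv", sep="\t")
        sig = filter_significant(enr)
        rollup = hierarchical_rollup(sig, ds.annotation.parents, ds.annotation, study)
    else:
        sig, rollup = pd.DataFrame(), {}

    summary = _summarize_run(ds, counts, mirna_de, mrna_de, cs, annotations, pair_table, sig, seed)
    summary["validator_ok"] = bool(
        pair_table.empty
        or validate_pair_table(pair_table, ds.mirna_seqs, ds.utrs, annotations, mfe_threshold)
    )
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(out / "run_log.json", "w") as fh:
        json.dump({"version": __version__, "seed": seed, "config": _jsonable(cfg)}, fh, indent=2, sort_keys=True)
    return summary


def stage_write_inputs(ds: SyntheticDataset, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    _write_fasta(out / "mirna_reference.fasta", {f"{m} {f}": s for m, f, s in zip(ds.reference.ids, ds.reference.families, ds.reference.sequences)})
    _write_fasta(out / "utrs.fasta", ds.utrs)
    ds.samples.to_csv(out / "samples_smallrna.tsv", sep="\t")
    ds.expr_samples.to_csv(out / "samples_array.tsv", sep="\t")
    ds.counts.to_csv(out / "true_counts.tsv", sep="\t")
    ds.expr.to_csv(out / "expression.tsv", sep="\t")
    _annotation_frame(ds.annotation).to_csv(out / "annotation.tsv", sep="\t", index=False)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(ds.truth.to_json_dict(), fh, indent=2, sort_keys=True)
    write_fastq_files(ds.config, ds.counts, ds.mirna_seqs, out / "fastq")


def _summarize_run(ds, counts, mirna_de, mrna_de, cs, annotations, pair_table, sig, seed) -> dict:
    truth = ds.truth
    planted_de = {m for v in truth.de_mirnas.values() for m in v}
    called_de = set(mirna_de.index[mirna_de["de_any"]])
    de_recovery = len(called_de & planted_de) / len(planted_de) if planted_de else float("nan")
    de_fdr = len(called_de - planted_de) / max(len(called_de), 1)
    planted_genes = {g for v in truth.anti_genes.values() for g in v}
    neg_genes = set(annotations.index[annotations["any_negative"]])
    gene_neg_recovery = len(neg_genes & planted_genes) / len(planted_genes) if planted_genes else float("nan")
    planted_pairs = {(m, g) for m, g, _p in truth.planted_pairs}
    found_pairs = set(zip(pair_table["mirna"], pair_table["gene"])) if not pair_table.empty else set()
    pair_recovery = len(found_pairs & planted_pairs) / len(planted_pairs) if planted_pairs else float("nan")
    shapes = {str(c): classify_archetype(cs.means.loc[c]) for c in cs.means.index}
    summary = {
        "seed": seed,
        "n_mirnas": int(counts.shape[0]),
        "n_samples": int(counts.shape[1]),
        "n_de_mirnas": int(len(called_de)),
        "n_de_genes": int(mrna_de["de_any"].sum()),
        "k_clusters": int(cs.k),
        "cluster_shapes": shapes,
        "n_negatively_correlated_genes": int(len(neg_genes)),
        "n_pair_rows": int(len(pair_table)),
        "n_pair_genes": int(pair_table["gene"].nunique()) if not pair_table.empty else 0,
        "n_pair_mirnas": int(pair_table["mirna"].nunique()) if not pair_table.empty else 0,
        "de_mirna_recovery": round(float(de_recovery), 4),
        "de_mirna_empirical_fdr": round(float(de_fdr), 4),
        "anticorrelated_gene_recovery": round(float(gene_neg_recovery), 4),
        "planted_pair_recovery": round(float(pair_recovery), 4),
        "n_enriched_terms": int(len(sig)),
        "planted_term_significant": bool("GO:PLANTED" in getattr(sig, "index", [])),
    }
    return summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
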