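"""Synthetic study generator.

Emulates the statistical structure the pipeline assumes, at desk scale:
a 6-timepoint (T1..T6) small-RNA count experiment with 8 replicates per
timepoint, negative-binomial counts, log-uniform per-sample size
factors, and three planted fold-change archetypes (sustained decrease;
transient dip one week post seawater transfer, T5; sustained increase);
a one-color microarray-like log2-intensity matrix whose planted genes
run anti-parallel to the archetype trajectories; 3'UTRs carrying
planted high-affinity seed sites for chosen (miRNA, gene) pairs, with
seed-free decoys; adapter-ligated 75 nt reads; and a gene-term
annotation table with one planted enriched term. A GroundTruth record
accompanies every dataset so recovery can be measured end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from . import targets as tg
from .enrich import AnnotationTable
from .quantify import DEFAULT_ADAPTER, MiRNAReference

ARCHETYPES = ("I", "II", "III")
TIMEPOINTS = ("T1", "T2", "T3", "T4", "T5", "T6")

DEFAULT_TRAJECTORIES: dict[str, tuple[float, ...]] = {
    # log2 fold change at T2..T6 relative to T1
    "I": (-0.6, -1.2, -1.8, -2.0, -2.4),
    "II": (-0.3, -0.2, -0.4, -1.8, -0.2),
    "III": (0.5, 1.0, 1.3, 1.6, 2.0),
}


@dataclass
class SimulationConfig:
    n_timepoints: int = 6
    n_replicates: int = 8
    n_array_replicates: int = 5
    n_mirnas: int = 80
    n_genes: int = 400
    n_de_per_archetype: tuple[int, int, int] = (12, 6, 10)
    n_anti_per_archetype: tuple[int, int, int] = (12, 0, 20)
    archetype_effects: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_TRAJECTORIES)
    )
    nb_dispersion: float = 0.05
    mean_count_range: tuple[float, float] = (100.0, 500.0)
    utr_length_range: tuple[int, int] = (200, 600)
    n_planted_pairs: int = 24
    mfe_margin: float = 4.0
    mfe_threshold: float = -18.0
    noise_sd: float = 0.25
    anticorr_gain: float = 1.0
    baseline_intensity_range: tuple[float, float] = (6.0, 12.0)
    contaminant_fraction: float = 0.02
    read_length: int = 75
    adapter: str = DEFAULT_ADAPTER
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_timepoints != 6:
            raise ValueError("design is fixed at 6 timepoints T1..T6")
        if self.n_replicates < 2:
            raise ValueError("n_replicates < 2 makes differential expression untestable")
        for name in ("n_mirnas", "n_genes", "n_array_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if sum(self.n_de_per_archetype) > self.n_mirnas:
            raise ValueError("more DE miRNAs requested than miRNAs simulated")
        if sum(self.n_anti_per_archetype) > self.n_genes:
            raise ValueError("more anti-correlated genes requested than genes simulated")
        if self.nb_dispersion < 0 or self.noise_sd < 0:
            raise ValueError("dispersion and noise SD must be non-negative")
        tI, tII, tIII = (np.asarray(self.archetype_effects[a]) for a in ARCHETYPES)
        if len(tI) != 5 or len(tII) != 5 or len(tIII) != 5:
            raise ValueError("archetype trajectories must cover T2..T6")
        if (np.diff(tI) > 1e-12).any() or tI[-1] > -1.0:
            raise ValueError("archetype I must be monotone non-increasing and <= -1 by T6")
        if tII.argmin() != 3 or abs(tII[3]) < 1.0 or (np.abs(np.delete(tII, 3)) >= 1.0).any():
            raise ValueError("archetype II must dip below |1| at T5 only")
        if tIII.max() < 1.0:
            raise ValueError("archetype III must reach +1 at some timepoint")
        if not 0.0 <= self.contaminant_fraction < 1.0:
            raise ValueError("contaminant fraction must lie in [0, 1)")

    def trajectory(self, archetype: str) -> np.ndarray:
        """log2FC at T1..T6 (T1 = 0 by definition)."""
        return np.concatenate([[0.0], np.asarray(self.archetype_effects[archetype], dtype=float)])


@dataclass
class GroundTruth:
    de_mirnas: dict[str, list[str]]  # archetype -> miRNA ids
    anti_genes: dict[str, list[str]]  # archetype -> gene ids
    planted_pairs: list[tuple[str, str, int]]  # (miRNA, gene, seed site pos, 1-based)
    null_mirnas: list[str]
    null_genes: list[str]

    def __post_init__(self):
        for d in (self.de_mirnas, self.anti_genes):
            ids = [x for v in d.values() for x in v]
            if len(ids) != len(set(ids)):
                raise ValueError("archetype id sets must be disjoint")
        de = {m for v in self.de_mirnas.values() for m in v}
        anti = {g for v in self.anti_genes.values() for g in v}
        for m, g, _pos in self.planted_pairs:
            if m not in de or g not in anti:
                raise ValueError(f"planted pair ({m}, {g}) references a non-planted id")

    def archetype_of_mirna(self) -> dict[str, str]:
        return {m: a for a, ms in self.de_mirnas.items() for m in ms}

    def archetype_of_gene(self) -> dict[str, str]:
        return {g: a for a, gs in self.anti_genes.items() for g in gs}

    def to_json_dict(self) -> dict:
        return {
            "de_mirnas": self.de_mirnas,
            "anti_genes": self.anti_genes,
            "planted_pairs": [list(p) for p in self.planted_pairs],
            "null_mirnas": self.null_mirnas,
            "null_genes": self.null_genes,
        }


def _sample_table(prefix: str, n_reps: int) -> pd.DataFrame:
    rows = [
        {"sample": f"{tp}_{prefix}{r + 1}", "timepoint": tp}
        for tp in TIMEPOINTS
        for r in range(n_reps)
    ]
    return pd.DataFrame(rows).set_index("sample")


def simulate_mirna_reference(config: SimulationConfig, rng: np.random.Generator) -> MiRNAReference:
    """Random mature 20-24-mers; two matures (5p/3p) share each family."""
    entries = []
    for i in range(config.n_mirnas):
        fam = f"fam-{i // 2:03d}"
        arm = "5p" if i % 2 == 0 else "3p"
        length = int(rng.integers(20, 25))
        seq = "".join(rng.choice(list("ACGU"), size=length))
        entries.append((f"sim-miR-{i // 2:03d}-{arm}", fam, seq))
    return MiRNAReference.from_entries(entries)


def simulate_mirna_counts(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    reference: MiRNAReference | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """NB count matrix (features x samples), sample table and ground truth.

    DE features follow mean_t = basemean * 2^trajectory(t); nulls stay
    flat. Per-sample size factors are log-uniform in [0.5, 2], making
    the normalization stage consequential.
    """
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    reference = reference if reference is not None else simulate_mirna_reference(config, rng)
    samples = _sample_table("r", config.n_replicates)
    ids = list(reference.ids)
    order = rng.permutation(config.n_mirnas)
    de_mirnas: dict[str, list[str]] = {}
    cursor = 0
    for a, n_de in zip(ARCHETYPES, config.n_de_per_archetype):
        de_mirnas[a] = sorted(ids[i] for i in order[cursor : cursor + n_de])
        cursor += n_de
    planted = {m for v in de_mirnas.values() for m in v}
    null_mirnas = sorted(set(ids) - planted)

    lo, hi = config.mean_count_range
    basemeans = np.exp(rng.uniform(math.log(lo), math.log(hi), size=config.n_mirnas))
    size_f = np.exp(rng.uniform(math.log(0.5), math.log(2.0), size=len(samples)))
    arch_of = {m: a for a, ms in de_mirnas.items() for m in ms}
    tp_index = np.array([TIMEPOINTS.index(tp) for tp in samples["timepoint"]])

    mat = np.zeros((config.n_mirnas, len(samples)), dtype=int)
    alpha = config.nb_dispersion
    for fi, mid in enumerate(ids):
        traj = config.trajectory(arch_of[mid]) if mid in arch_of else np.zeros(6)
        mean_per_sample = basemeans[fi] * np.power(2.0, traj[tp_index]) * size_f
        if alpha <= 1e-12:
            mat[fi] = rng.poisson(mean_per_sample)
        else:
            n_param = 1.0 / alpha
            p_param = n_param / (n_param + mean_per_sample)
            mat[fi] = rng.negative_binomial(n_param, p_param)
    counts = pd.DataFrame(mat, index=ids, columns=samples.index)
    counts.index.name = "feature"
    truth = GroundTruth(
        de_mirnas=de_mirnas,
        anti_genes={a: [] for a in ARCHETYPES},
        planted_pairs=[],
        null_mirnas=null_mirnas,
        null_genes=[],
    )
    return counts, samples, truth


def expected_planted_correlation(config: SimulationConfig, archetype: str) -> float:
    """Expected |Pearson r| of a planted gene profile vs its cluster mean."""
    prof = config.anticorr_gain * np.asarray(config.archetype_effects[archetype], dtype=float)
    vp = prof.var()
    noise_var = config.noise_sd**2 * 2.0 / config.n_array_replicates
    return math.sqrt(vp / (vp + noise_var)) if vp > 0 else 0.0


def simulate_mrna_expression(
    config: SimulationConfig,
    truth: GroundTruth,
    cluster_means: Mapping[str, np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log2-intensity matrix (genes x arrays) with planted anti-correlation.

    Planted genes follow baseline - gain * (cluster mean trajectory)
    plus Gaussian noise; background genes are noise around baseline.
    """
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed + 1)
    for a in ARCHETYPES:
        if truth.anti_genes[a] and expected_planted_correlation(config, a) < 0.67:
            raise ValueError(
                f"noise SD {config.noise_sd} makes expected |r| < 0.67 for archetype {a}: "
                "planted truth would be unrecoverable"
            )
    means = (
        {a: np.asarray(cluster_means[a], dtype=float) for a in ARCHETYPES}
        if cluster_means is not None
        else {a: np.asarray(config.archetype_effects[a], dtype=float) for a in ARCHETYPES}
    )
    samples = _sample_table("a", config.n_array_replicates)
    genes = [f"gene-{i:04d}" for i in range(config.n_genes)]
    lo, hi = config.baseline_intensity_range
    baseline = rng.uniform(lo, hi, size=config.n_genes)
    tp_index = np.array([TIMEPOINTS.index(tp) for tp in samples["timepoint"]])
    arch_of = truth.archetype_of_gene()
    mat = np.empty((config.n_genes, len(samples)))
    for gi, gene in enumerate(genes):
        if gene in arch_of:
            traj = np.concatenate([[0.0], means[arch_of[gene]]])
            signal = baseline[gi] - config.anticorr_gain * traj[tp_index]
        else:
            signal = np.full(len(samples), baseline[gi])
        mat[gi] = signal + rng.normal(0.0, config.noise_sd, size=len(samples))
    expr = pd.DataFrame(mat, index=genes, columns=samples.index)
    expr.index.name = "gene"
    return expr, samples


def assign_anti_genes(config: SimulationConfig, truth: GroundTruth, rng: np.random.Generator) -> GroundTruth:
    """Pick disjoint anti-correlated gene sets and the planted pair list."""
    genes = [f"gene-{i:04d}" for i in range(config.n_genes)]
    order = rng.permutation(config.n_genes)
    cursor = 0
    anti: dict[str, list[str]] = {}
    for a, n_a in zip(ARCHETYPES, config.n_anti_per_archetype):
        anti[a] = sorted(genes[i] for i in order[cursor : cursor + n_a])
        cursor += n_a
    planted_genes = {g for v in anti.values() for g in v}
    truth.anti_genes = anti
    truth.null_genes = sorted(set(genes) - planted_genes)

    pairs: list[tuple[str, str, int]] = []
    candidates = [
        (a, g) for a in ARCHETYPES for g in anti[a] if truth.de_mirnas[a]
    ]
    if config.n_planted_pairs and not candidates:
        raise ValueError("planted pairs requested but no archetype has both miRNAs and genes")
    for idx in range(config.n_planted_pairs):
        a, g = candidates[idx % len(candidates)]
        m = truth.de_mirnas[a][int(rng.integers(len(truth.de_mirnas[a])))]
        if any(p[0] == m and p[1] == g for p in pairs):
            m = truth.de_mirnas[a][(truth.de_mirnas[a].index(m) + 1) % len(truth.de_mirnas[a])]
            if any(p[0] == m and p[1] == g for p in pairs):
                continue
        pairs.append((m, g, 0))  # site positions filled in by simulate_utrs
    truth.planted_pairs = pairs
    return truth


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


def _seed_motifs(mirna_seqs: Mapping[str, str], mirnas: set[str]) -> dict[str, str]:
    return {m: tg.reverse_complement(tg.normalize_rna(mirna_seqs[m])[1:8]) for m in mirnas}


def simulate_utrs(
    config: SimulationConfig,
    truth: GroundTruth,
    mirna_seqs: Mapping[str, str],
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """3'UTR per gene: planted high-affinity sites, seed-free decoys.

    A planted site is the full reverse complement of its miRNA, which
    under the shipped energy model sits far below the reporting
    threshold; construction is verified against the duplex DP and the
    seed position is recorded in the ground truth. Decoy UTRs are
    redrawn (up to 100 times) until they contain no 7-mer seed
    complement of any planted miRNA.
    """
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed + 2)
    planted_mirnas = {m for m, _g, _p in truth.planted_pairs}
    motifs = _seed_motifs(mirna_seqs, planted_mirnas)
    by_gene: dict[str, list[int]] = {}
    for i, (m, g, _pos) in enumerate(truth.planted_pairs):
        by_gene.setdefault(g, []).append(i)
    lo, hi = config.utr_length_range
    utrs: dict[str, str] = {}
    genes = [f"gene-{i:04d}" for i in range(config.n_genes)]
    for gene in genes:
        length = int(rng.integers(lo, hi + 1))
        if gene in by_gene:
            utrs[gene] = _build_planted_utr(config, truth, gene, by_gene[gene], mirna_seqs, motifs, length, rng)
        else:
            utrs[gene] = _build_decoy_utr(motifs, length, rng, gene)
    return utrs


def _build_decoy_utr(motifs: Mapping[str, str], length: int, rng: np.random.Generator, gene: str) -> str:
    for _attempt in range(100):
        seq = _random_seq(rng, length)
        if not any(motif in seq for motif in motifs.values()):
            return seq
    raise RuntimeError(f"could not build a seed-free decoy UTR for {gene} in 100 attempts")


def _build_planted_utr(
    config: SimulationConfig,
    truth: GroundTruth,
    gene: str,
    pair_indices: list[int],
    mirna_seqs: Mapping[str, str],
    motifs: Mapping[str, str],
    length: int,
    rng: np.random.Generator,
) -> str:
    inserts = []
    for idx in pair_indices:
        m = truth.planted_pairs[idx][0]
        inserts.append((idx, m, tg.reverse_complement(mirna_seqs[m])))
    needed = sum(len(ins) for _, _, ins in inserts)
    length = max(length, needed + 40 * len(inserts))
    backbone = _build_decoy_utr(motifs, length - needed, rng, gene)
    # spread sites through the backbone at deterministic offsets
    gap = len(backbone) // (len(inserts) + 1)
    seq = ""
    consumed = 0
    for slot, (idx, m, insert) in enumerate(inserts, start=1):
        cut = slot * gap
        seq += backbone[consumed:cut] + insert
        consumed = cut
        site_start_0 = len(seq) - len(insert)
        mlen = len(tg.normalize_rna(mirna_seqs[m]))
        seed_pos = site_start_0 + (mlen - 8) + 1  # 1-based seed-match start
        truth.planted_pairs[idx] = (m, gene, seed_pos)
    seq += backbone[consumed:]
    for idx in pair_indices:
        m, g, pos = truth.planted_pairs[idx]
        sites = tg.find_seed_sites(seq, mirna_seqs[m])
        if pos not in sites:
            raise RuntimeError(f"planted seed site lost during UTR assembly for ({m}, {g})")
        window_lo = max(0, pos - 1 - (len(mirna_seqs[m]) + 9))
        window = seq[window_lo : pos + 6 + len(mirna_seqs[m]) + 9]
        st = tg.duplex_mfe(window, mirna_seqs[m])
        if not st.mfe <= config.mfe_threshold - config.mfe_margin:
            raise RuntimeError(
                f"planted site for ({m}, {g}) scored {st.mfe:.2f}, above "
                f"{config.mfe_threshold - config.mfe_margin}"
            )
    return seq


def reads_for_sample(
    config: SimulationConfig,
    counts: pd.Series,
    mirna_seqs: Mapping[str, str],
    rng: np.random.Generator,
) -> Iterator[tuple[str, str, str]]:
    """(title, sequence, quality) tuples for one sample's FASTQ."""
    L = config.read_length
    qual = "I" * L  # phred 40, comfortably above the QC floor of 32
    n_real = int(counts.sum())
    read_no = 0
    for mid, c in counts.items():
        if c <= 0:
            continue
        insert = tg.normalize_rna(mirna_seqs[mid]).replace("U", "T")
        seq = (insert + config.adapter).ljust(L, "A")[:L]
        for _ in range(int(c)):
            read_no += 1
            yield f"read{read_no}_{mid}", seq, qual
    f = config.contaminant_fraction
    if f > 0 and n_real > 0:
        n_total = round(n_real / (1.0 - f))
        n_cont = int(rng.binomial(n_total, f))
        for _ in range(n_cont):
            read_no += 1
            short = rng.random() < 0.5
            ins_len = int(rng.integers(8, 18)) if short else int(rng.integers(26, 41))
            insert = _random_seq(rng, ins_len).replace("U", "T")
            seq = (insert + config.adapter).ljust(L, "A")[:L]
            yield f"read{read_no}_contaminant", seq, qual


def write_fastq_files(
    config: SimulationConfig,
    counts: pd.DataFrame,
    mirna_seqs: Mapping[str, str],
    out_dir: str | Path,
    rng: np.random.Generator | None = None,
) -> dict[str, Path]:
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed + 3)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sample in counts.columns:
        path = out_dir / f"{sample}.fastq"
        with open(path, "w") as fh:
            for title, seq, qual in reads_for_sample(config, counts[sample], mirna_seqs, rng):
                fh.write(f"@{title}\n{seq}\n+\n{qual}\n")
        paths[sample] = path
    return paths


PLANTED_TERM = "GO:PLANTED"


def simulate_annotation(
    config: SimulationConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
    n_terms: int = 50,
) -> AnnotationTable:
    """Gene-term table with one planted enriched term over planted-pair genes."""
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed + 4)
    genes = [f"gene-{i:04d}" for i in range(config.n_genes)]
    terms = [f"GO:D{i:03d}" for i in range(n_terms)]
    parents = {t: {f"GO:P{i % 5}"} for i, t in enumerate(terms)}
    gene_terms: dict[str, set[str]] = {}
    for g in genes:
        k = 1 + int(rng.integers(0, 4))
        gene_terms[g] = set(rng.choice(terms, size=k, replace=False))
    target_genes = {g for _m, g, _p in truth.planted_pairs}
    for g in target_genes:
        gene_terms[g].add(PLANTED_TERM)
    for g in rng.choice(genes, size=max(1, config.n_genes // 100), replace=False):
        gene_terms[g].add(PLANTED_TERM)
    names = {t: f"decoy process {t[-3:]}" for t in terms}
    names[PLANTED_TERM] = "planted regulated process"
    return AnnotationTable(gene_terms, names, parents)


@dataclass
class SyntheticDataset:
    """Everything a pipeline run needs, in memory."""

    config: SimulationConfig
    reference: MiRNAReference
    counts: pd.DataFrame
    samples: pd.DataFrame
    expr: pd.DataFrame
    expr_samples: pd.DataFrame
    utrs: dict[str, str]
    annotation: AnnotationTable
    truth: GroundTruth

    @property
    def mirna_seqs(self) -> dict[str, str]:
        return {m: s for m, s in zip(self.reference.ids, self.reference.sequences)}


def simulate_all(config: SimulationConfig) -> SyntheticDataset:
    """Deterministic full dataset from one seed."""
    rng = np.random.default_rng(config.rng_seed)
    reference = simulate_mirna_reference(config, rng)
    counts, samples, truth = simulate_mirna_counts(config, rng, reference)
    truth = assign_anti_genes(config, truth, rng)
    expr, expr_samples = simulate_mrna_expression(config, truth, rng=rng)
    seqs = {m: s for m, s in zip(reference.ids, reference.sequences)}
    utrs = simulate_utrs(config, truth, seqs, rng)
    annotation = simulate_annotation(config, truth, rng)
    return SyntheticDataset(
        config=config,
        reference=reference,
        counts=counts,
        samples=samples,
        expr=expr,
        expr_samples=expr_samples,
        utrs=utrs,
        annotation=annotation,
        truth=truth,
    )


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    for key in ("n_de_per_archetype", "n_anti_per_archetype", "mean_count_range", "utr_length_range", "baseline_intensity_range"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    if "archetype_effects" in d:
        d["archetype_effects"] = {a: tuple(v) for a, v in d["archetype_effects"].items()}
    return SimulationConfig(**d)


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
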