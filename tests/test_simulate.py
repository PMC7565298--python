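"""Synthetic-data generator: determinism, distributions, construction guarantees."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, poisson

from smoltmir.quantify import quantify_sample
from smoltmir.simulate import (
    DEFAULT_TRAJECTORIES,
    GroundTruth,
    SimulationConfig,
    reads_for_sample,
    simulate_all,
    simulate_mirna_counts,
    simulate_mrna_expression,
    write_fastq_files,
)


class TestConfigValidation:
    def test_defaults_are_valid(self):
        SimulationConfig()

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="untestable"):
            SimulationConfig(n_replicates=1)

    def test_archetype_one_must_be_monotone(self):
        bad = dict(DEFAULT_TRAJECTORIES, I=(-0.5, -1.0, -1.5, -1.2, -2.0))
        with pytest.raises(ValueError, match="monotone"):
            SimulationConfig(archetype_effects=bad)

    def test_archetype_two_needs_t5_dip(self):
        bad = dict(DEFAULT_TRAJECTORIES, II=(-1.5, -0.2, -0.4, -1.8, -0.2))
        with pytest.raises(ValueError, match="T5"):
            SimulationConfig(archetype_effects=bad)

    def test_more_de_than_mirnas_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_mirnas=5, n_de_per_archetype=(3, 3, 3))


class TestGroundTruthInvariants:
    def test_archetype_sets_must_be_disjoint(self):
        with pytest.raises(ValueError, match="disjoint"):
            GroundTruth(
                de_mirnas={"I": ["m1"], "II": ["m1"], "III": []},
                anti_genes={"I": [], "II": [], "III": []},
                planted_pairs=[],
                null_mirnas=[],
                null_genes=[],
            )

    def test_planted_pairs_must_reference_planted_ids(self):
        with pytest.raises(ValueError, match="non-planted"):
            GroundTruth(
                de_mirnas={"I": ["m1"], "II": [], "III": []},
                anti_genes={"I": ["g1"], "II": [], "III": []},
                planted_pairs=[("m1", "g-unknown", 1)],
                null_mirnas=[],
                null_genes=[],
            )


class TestCounts:
    def test_same_seed_bitwise_identical(self):
        cfg = SimulationConfig(n_mirnas=20, rng_seed=9, n_de_per_archetype=(2, 2, 2), n_anti_per_archetype=(2, 0, 2), n_planted_pairs=2)
        c1, s1, _ = simulate_mirna_counts(cfg)
        c2, s2, _ = simulate_mirna_counts(cfg)
        assert c1.equals(c2) and s1.equals(s2)

    def test_all_null_features_have_small_fold_changes(self):
        cfg = SimulationConfig(
            n_mirnas=2000,
            n_de_per_archetype=(0, 0, 0),
            n_anti_per_archetype=(0, 0, 0),
            n_planted_pairs=0,
            mean_count_range=(100.0, 500.0),
            rng_seed=3,
        )
        counts, samples, _ = simulate_mirna_counts(cfg)
        t1 = samples.index[samples["timepoint"] == "T1"]
        t6 = samples.index[samples["timepoint"] == "T6"]
        from smoltmir.diffexpr import size_factors

        norm = counts / size_factors(counts)
        lfc = np.log2(norm[t6].mean(axis=1) + 0.5) - np.log2(norm[t1].mean(axis=1) + 0.5)
        assert (lfc.abs() <= 0.5).mean() >= 0.95

    def test_zero_dispersion_matches_poisson_envelope(self):
        cfg = SimulationConfig(
            n_mirnas=500,
            n_de_per_archetype=(0, 0, 0),
            n_anti_per_archetype=(0, 0, 0),
            n_planted_pairs=0,
            nb_dispersion=0.0,
            mean_count_range=(100.0, 100.0),
            rng_seed=4,
        )
        counts, samples, _ = simulate_mirna_counts(cfg)
        # recover the per-sample scale from the data itself
        sf = counts.mean(axis=0) / 100.0
        lo = poisson.ppf(0.0005, 100.0 * sf)
        hi = poisson.ppf(0.9995, 100.0 * sf)
        outside = ((counts < lo) | (counts > hi)).to_numpy().mean()
        assert outside <= 0.005


class TestExpression:
    def test_zero_noise_gives_exact_anticorrelation(self):
        cfg = SimulationConfig(
            n_mirnas=12,
            n_genes=30,
            n_de_per_archetype=(2, 2, 2),
            n_anti_per_archetype=(3, 0, 3),
            n_planted_pairs=4,
            noise_sd=0.0,
            rng_seed=5,
        )
        rng = np.random.default_rng(5)
        from smoltmir.simulate import assign_anti_genes, simulate_mirna_reference

        ref = simulate_mirna_reference(cfg, rng)
        _, _, truth = simulate_mirna_counts(cfg, rng, ref)
        truth = assign_anti_genes(cfg, truth, rng)
        expr, samples = simulate_mrna_expression(cfg, truth, rng=rng)
        for archetype in ("I", "III"):
            traj = np.asarray(cfg.archetype_effects[archetype])
            for gene in truth.anti_genes[archetype]:
                prof = expr.loc[gene].groupby(samples["timepoint"]).mean()
                lfc = (prof[[f"T{i}" for i in range(2, 7)]] - prof["T1"]).to_numpy()
                r = np.corrcoef(lfc, traj)[0, 1]
                assert r == pytest.approx(-1.0)

    def test_unrecoverable_noise_rejected(self):
        cfg = SimulationConfig(noise_sd=5.0, rng_seed=0)
        truth = GroundTruth(
            de_mirnas={"I": [], "II": [], "III": []},
            anti_genes={"I": ["gene-0001"], "II": [], "III": []},
            planted_pairs=[],
            null_mirnas=[],
            null_genes=[],
        )
        with pytest.raises(ValueError, match="unrecoverable"):
            simulate_mrna_expression(cfg, truth)


class TestReads:
    def _tiny(self, **kw):
        kw.setdefault("n_mirnas", 6)
        kw.setdefault("n_genes", 10)
        kw.setdefault("n_de_per_archetype", (1, 1, 1))
        kw.setdefault("n_anti_per_archetype", (1, 0, 1))
        kw.setdefault("n_planted_pairs", 2)
        kw.setdefault("mean_count_range", (30.0, 60.0))
        return SimulationConfig(**kw)

    def test_zero_contaminants_round_trips_exactly(self, tmp_path):
        cfg = self._tiny(contaminant_fraction=0.0, rng_seed=6)
        ds = simulate_all(cfg)
        paths = write_fastq_files(cfg, ds.counts, ds.mirna_seqs, tmp_path)
        sample = ds.counts.columns[0]
        counts, stats = quantify_sample(paths[sample], ds.reference)
        recovered = pd.Series(counts).reindex(ds.counts.index).fillna(0).astype(int)
        assert recovered.equals(ds.counts[sample])
        assert stats.conserves() and stats.multi_hit == 0

    def test_trimmed_length_equals_mirna_length(self):
        cfg = self._tiny(contaminant_fraction=0.0, rng_seed=7)
        ds = simulate_all(cfg)
        rng = np.random.default_rng(0)
        mid = ds.reference.ids[0]
        series = pd.Series(0, index=ds.reference.ids)
        series[mid] = 3
        from smoltmir.quantify import trim_adapter

        for _title, seq, qual in reads_for_sample(cfg, series, ds.mirna_seqs, rng):
            assert len(seq) == 75 and set(qual) == {"I"}
            assert len(trim_adapter(seq)) == len(ds.mirna_seqs[mid])

    def test_contaminant_fraction_within_binomial_ci(self):
        cfg = self._tiny(contaminant_fraction=0.2, rng_seed=8)
        ds = simulate_all(cfg)
        rng = np.random.default_rng(1)
        series = pd.Series(0, index=ds.reference.ids)
        series[ds.reference.ids[0]] = 10_000
        n_cont = n_total = 0
        for title, seq, _q in reads_for_sample(cfg, series, ds.mirna_seqs, rng):
            n_total += 1
            n_cont += title.endswith("contaminant")
        lo, hi = binom.ppf([0.005, 0.995], n_total, 0.2) / n_total
        assert lo <= n_cont / n_total <= hi


def test_full_dataset_determinism():
    cfg = SimulationConfig(
        n_mirnas=10,
        n_genes=20,
        n_de_per_archetype=(2, 1, 2),
        n_anti_per_archetype=(2, 0, 3),
        n_planted_pairs=4,
        rng_seed=11,
    )
    d1, d2 = simulate_all(cfg), simulate_all(cfg)
    assert d1.counts.equals(d2.counts)
    assert d1.expr.equals(d2.expr)
    assert d1.utrs == d2.utrs
    assert d1.truth.planted_pairs == d2.truth.planted_pairs


def test_planted_sites_beat_threshold_with_margin(small_dataset):
    from smoltmir.targets import duplex_mfe

    ds = small_dataset
    for m, g, pos in ds.truth.planted_pairs:
        utr = ds.utrs[g]
        mlen = len(ds.mirna_seqs[m])
        window = utr[max(0, pos - 1 - (mlen + 9)) : pos + 6 + mlen + 9]
        st = duplex_mfe(window, ds.mirna_seqs[m])
        assert st.mfe <= ds.config.mfe_threshold - ds.config.mfe_margin


def test_decoy_utrs_are_seed_free(small_dataset):
    from smoltmir.targets import find_seed_sites

    ds = small_dataset
    planted_mirnas = {m for m, _g, _p in ds.truth.planted_pairs}
    for g in ds.truth.null_genes[:30]:
        for m in planted_mirnas:
            assert find_seed_sites(ds.utrs[g], ds.mirna_seqs[m]) == []
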