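"""Seed matching and duplex-MFE prediction."""

import math

import numpy as np
import pytest

from oracles import brute_force_duplex_mfe, naive_seed_scan, random_rna
from smoltmir.energy import DEFAULT_MODEL, WATSON_CRICK
from smoltmir.targets import (
    duplex_mfe,
    find_seed_sites,
    predict_targets,
    reverse_complement,
    score_structure,
)

LET7_LIKE = "UGAGGUAGUAGGUUGUAUAGUU"  # seed (pos 2-8) GAGGUAG


class TestSeedSites:
    def test_reverse_complement_construction_yields_one_site(self):
        utr = "AAAA" + "CUACCUC" + "GGGG"  # CUACCUC = revcomp of GAGGUAG
        assert find_seed_sites(utr, LET7_LIKE) == [5]

    def test_gu_wobble_is_not_a_seed_match(self):
        # CUGCCUC would pair GAGGUAG only via a G:U at one position
        utr = "AAAA" + "CUGCCUC" + "GGGG"
        assert find_seed_sites(utr, LET7_LIKE) == []

    def test_dna_input_and_case_are_normalized(self):
        utr = "aaaa" + "ctacctc" + "gggg"
        assert find_seed_sites(utr, LET7_LIKE.replace("U", "T").lower()) == [5]

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError):
            find_seed_sites("ACGUACGUACGU", "ACGUA")

    @pytest.mark.parametrize("seed_val", range(5))
    def test_matches_naive_sliding_window_scan(self, seed_val):
        rng = np.random.default_rng(seed_val)
        mirna = random_rna(rng, 22)
        utr = random_rna(rng, 2000)
        assert find_seed_sites(utr, mirna) == naive_seed_scan(utr, mirna)


class TestScoreStructure:
    def test_full_complement_equals_hand_sum_over_constants(self):
        mirna = LET7_LIKE
        window = reverse_complement(mirna)
        m = len(mirna)
        pairs = [(i, m - i + 1) for i in range(1, m + 1)]
        expected = DEFAULT_MODEL.init
        for i in range(1, m):
            top5, top3 = mirna[i - 1], mirna[i]
            bot5, bot3 = window[m - i], window[m - i - 1]
            expected += DEFAULT_MODEL.stacks[f"{top5}{top3}/{bot5}{bot3}"]
        for end in (0, -1):
            expected += DEFAULT_MODEL.terminal_penalty(mirna[end], window[-(end + 1)])
        assert score_structure(pairs, mirna, window) == pytest.approx(expected)

    def test_crossing_pairs_rejected(self):
        with pytest.raises(ValueError):
            score_structure([(1, 2), (2, 5)], "ACGUACGU", "ACGUACGU")


class TestDuplexMFE:
    def test_full_complement_duplex_matches_scorer(self):
        window = "AAAAA" + reverse_complement(LET7_LIKE) + "AAAAA"
        st = duplex_mfe(window, LET7_LIKE)
        assert st.is_hit
        assert st.mfe == pytest.approx(score_structure(st.pairs, LET7_LIKE, window))
        # positions 2-8 all paired contiguously
        seed_pairs = sorted(j for i, j in st.pairs if 2 <= i <= 8)
        assert len(seed_pairs) == 7
        assert seed_pairs == list(range(seed_pairs[0], seed_pairs[0] + 7))

    def test_seed_only_duplex_equals_hand_sum(self):
        # miRNA with inert (A) flanks against an inert window: only the
        # seed helix can form, so MFE = init + 6 seed stacks + terminal ends.
        mirna = "A" + "GAGGUAG" + "A" * 14
        window = "AAAA" + reverse_complement("GAGGUAG") + "AAAA"
        st = duplex_mfe(window, mirna)
        expected = DEFAULT_MODEL.init
        site = reverse_complement("GAGGUAG")
        for k in range(7 - 1):
            expected += DEFAULT_MODEL.stacks[f"{mirna[k + 1]}{mirna[k + 2]}/{site[6 - k]}{site[5 - k]}"]
        expected += DEFAULT_MODEL.terminal_penalty("G", "C")  # pair at miRNA pos 2
        expected += DEFAULT_MODEL.terminal_penalty("G", "C")  # pair at miRNA pos 8
        assert st.mfe == pytest.approx(expected)
        assert sorted(i for i, _ in st.pairs) == list(range(2, 9))

    def test_no_seed_site_returns_sentinel(self):
        st = duplex_mfe("A" * 40, LET7_LIKE)
        assert not st.is_hit and math.isinf(st.mfe)

    @pytest.mark.parametrize("trial_seed", range(40))
    def test_unconstrained_dp_equals_brute_force(self, trial_seed):
        rng = np.random.default_rng(trial_seed)
        mirna = random_rna(rng, int(rng.integers(4, 8)))
        window = random_rna(rng, int(rng.integers(6, 13)))
        st = duplex_mfe(window, mirna, helix_constraint=None)
        oracle = brute_force_duplex_mfe(window, mirna)
        if math.isinf(oracle):
            assert not st.is_hit
        else:
            assert st.mfe == pytest.approx(oracle, abs=1e-9)

    @pytest.mark.parametrize("trial_seed", range(20))
    def test_anchored_dp_equals_constrained_brute_force(self, trial_seed):
        rng = np.random.default_rng(100 + trial_seed)
        mirna = random_rna(rng, 10)
        window = random_rna(rng, 3) + reverse_complement(mirna[1:8]) + random_rna(rng, 3)
        st = duplex_mfe(window, mirna)
        oracle = brute_force_duplex_mfe(window, mirna, require_helix=(2, 8))
        assert st.mfe == pytest.approx(oracle, abs=1e-9)
        assert st.mfe == pytest.approx(score_structure(st.pairs, mirna, window))

    def test_appending_complementary_bases_never_raises_mfe(self, rng):
        mirna = random_rna(rng, 12)
        base_window = reverse_complement(mirna[1:8])
        prev = duplex_mfe(base_window, mirna).mfe
        # grow the complementary region one base at a time toward the 3' end
        for extra in range(1, 5):
            window = reverse_complement(mirna[1 : 8 + extra])
            cur = duplex_mfe(window, mirna).mfe
            assert cur <= prev + 1e-9
            prev = cur


class TestPredictTargets:
    def test_threshold_is_inclusive_and_strict_above(self):
        utr = "AAAA" + reverse_complement(LET7_LIKE) + "AAAA"
        mfe = duplex_mfe(utr, LET7_LIKE).mfe
        at_bound = predict_targets({"m": LET7_LIKE}, {"g": utr}, mfe_threshold=mfe)
        above_bound = predict_targets({"m": LET7_LIKE}, {"g": utr}, mfe_threshold=mfe - 0.01)
        assert len(at_bound) == 1 and len(above_bound) == 0

    def test_planted_site_reported_and_decoys_clean(self, small_dataset):
        ds = small_dataset
        seqs = ds.mirna_seqs
        planted_pairs = {(m, g) for m, g, _ in ds.truth.planted_pairs}
        mirna_ids = sorted({m for m, _, _ in ds.truth.planted_pairs})
        genes = sorted({g for _, g, _ in ds.truth.planted_pairs})
        decoys = ds.truth.null_genes[:20]
        utrs = {g: ds.utrs[g] for g in genes + decoys}
        hits = predict_targets({m: seqs[m] for m in mirna_ids}, utrs)
        found = {(h.mirna_id, h.utr_id) for h in hits}
        assert planted_pairs <= found
        assert not any(h.utr_id in decoys for h in hits)

    def test_planted_seed_positions_match_ground_truth(self, small_dataset):
        ds = small_dataset
        for m, g, pos in ds.truth.planted_pairs:
            assert pos in find_seed_sites(ds.utrs[g], ds.mirna_seqs[m])

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            predict_targets({}, {"g": "ACGU"})


def test_every_watson_crick_stack_is_stabilizing():
    for x, w in WATSON_CRICK:
        for y, z in WATSON_CRICK:
            assert DEFAULT_MODEL.stacks[f"{x}{y}/{w}{z}"] < 0


def test_loop_penalties_monotone_non_decreasing():
    assert all(b <= a for b, a in zip(DEFAULT_MODEL.bulge, DEFAULT_MODEL.bulge[1:]))
    assert all(b <= a for b, a in zip(DEFAULT_MODEL.internal, DEFAULT_MODEL.internal[1:]))
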