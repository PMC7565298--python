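"""Normalization, NB Wald test, Welch t-test and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from oracles import bh_stepup
from smoltmir.diffexpr import (
    apply_de_filters,
    bh_adjust,
    de_mirna,
    nb_wald_test,
    size_factors,
    ttest_expr,
)


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        df = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
        assert np.allclose(size_factors(df), [1.0, 1.0])

    def test_doubled_sample_gives_factor_ratio_two(self):
        df = pd.DataFrame({"a": [10, 20, 5, 8], "b": [20, 40, 10, 16]})
        f = size_factors(df)
        assert f["b"] / f["a"] == pytest.approx(2.0)
        assert np.exp(np.log(f).mean()) == pytest.approx(1.0)

    def test_matches_hand_computed_median_of_ratios(self):
        # every feature has exact column ratios 1:2:3, so the median
        # ratio per column is c / 6^(1/3); rescaling keeps exactly that
        df = pd.DataFrame(
            {"s1": [10, 20, 5, 8, 100], "s2": [20, 40, 10, 16, 200], "s3": [30, 60, 15, 24, 300]}
        )
        expected = np.array([1.0, 2.0, 3.0]) / 6 ** (1 / 3)
        assert np.allclose(size_factors(df), expected)

    def test_no_all_positive_feature_raises(self):
        df = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(df)


class TestNBWald:
    def test_identical_groups_give_null_result(self):
        vals = np.tile([[10, 12, 9, 11]], (5, 1))
        df = pd.DataFrame(np.hstack([vals, vals]), columns=list("abcdefgh"))
        f = pd.Series(1.0, index=df.columns)
        res = nb_wald_test(df, list("abcd"), list("efgh"), f)
        assert np.allclose(res["log2FC"], 0.0)
        assert np.allclose(res["p"], 1.0)

    def test_null_type_one_error_is_calibrated(self, rng):
        mu = np.exp(rng.uniform(np.log(20), np.log(500), 2000))
        n_param = 1 / 0.05
        counts = rng.negative_binomial(n_param, n_param / (n_param + mu[:, None]), size=(2000, 16))
        df = pd.DataFrame(counts, columns=[f"s{i}" for i in range(16)])
        res = nb_wald_test(df, [f"s{i}" for i in range(8)], [f"s{i}" for i in range(8, 16)], size_factors(df))
        assert 0.03 <= (res["p"] < 0.05).mean() <= 0.07

    def test_planted_effect_recovered(self, rng):
        mu = np.full(500, 200.0)
        n_param = 1 / 0.05
        A = rng.negative_binomial(n_param, n_param / (n_param + mu[:, None]), size=(500, 8))
        B = rng.negative_binomial(n_param, n_param / (n_param + (mu / 4)[:, None]), size=(500, 8))
        df = pd.DataFrame(np.hstack([A, B]), columns=[f"s{i}" for i in range(16)])
        res = nb_wald_test(df, [f"s{i}" for i in range(8)], [f"s{i}" for i in range(8, 16)], pd.Series(1.0, index=df.columns))
        assert res["log2FC"].mean() == pytest.approx(-2.0, abs=0.3)

    def test_normalization_invariance_under_sample_scaling(self, rng):
        mu = np.exp(rng.uniform(np.log(50), np.log(300), 100))
        n_param = 1 / 0.05
        counts = rng.negative_binomial(n_param, n_param / (n_param + mu[:, None]), size=(100, 16))
        df = pd.DataFrame(counts, columns=[f"s{i}" for i in range(16)])
        scaled = df.copy()
        scaled["s3"] = (scaled["s3"] * 3).astype(int)
        a, b = [f"s{i}" for i in range(8)], [f"s{i}" for i in range(8, 16)]
        r1 = nb_wald_test(df, a, b, size_factors(df))
        r2 = nb_wald_test(scaled, a, b, size_factors(scaled))
        # exact c-fold scaling commutes with median-of-ratios, so fold
        # changes shift only by rounding of the scaled integer counts
        assert np.abs(r1["log2FC"] - r2["log2FC"]).max() < 0.05

    def test_too_few_replicates_rejected(self):
        df = pd.DataFrame({"a": [1, 2], "b": [3, 4]})
        with pytest.raises(ValueError):
            nb_wald_test(df, ["a"], ["b"], pd.Series(1.0, index=["a", "b"]))


class TestTTest:
    def test_exact_unit_shift_with_zero_variance(self):
        expr = pd.DataFrame({"a1": [1.0], "a2": [1.0], "b1": [2.0], "b2": [2.0]})
        res = ttest_expr(expr, ["a1", "a2"], ["b1", "b2"])
        assert res["log2FC"].iloc[0] == pytest.approx(1.0)

    def test_matches_textbook_welch_formula(self):
        a, b = np.array([1.0, 2.0]), np.array([3.0, 5.0])
        expr = pd.DataFrame([np.concatenate([a, b])], columns=["a1", "a2", "b1", "b2"])
        res = ttest_expr(expr, ["a1", "a2"], ["b1", "b2"])
        se = np.sqrt(a.var(ddof=1) / 2 + b.var(ddof=1) / 2)
        t = (b.mean() - a.mean()) / se
        df_w = se**4 / ((a.var(ddof=1) / 2) ** 2 / 1 + (b.var(ddof=1) / 2) ** 2 / 1)
        p = 2 * sps.t.sf(abs(t), df_w)
        assert res["t"].iloc[0] == pytest.approx(t)
        assert res["p"].iloc[0] == pytest.approx(p)

    def test_null_pvalues_uniform(self, rng):
        expr = pd.DataFrame(rng.normal(size=(10000, 10)), columns=[f"s{i}" for i in range(10)])
        res = ttest_expr(expr, [f"s{i}" for i in range(5)], [f"s{i}" for i in range(5, 10)])
        ks = sps.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.01


class TestBH:
    def test_single_pvalue_identity(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_worked_stepup_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, float("nan")])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
    def test_matches_stepup_oracle_and_bounds(self, pvals):
        adj = bh_adjust(pvals)
        assert np.allclose(adj, bh_stepup(np.array(pvals)))
        assert (adj >= np.asarray(pvals) - 1e-12).all() and (adj <= 1.0).all()

    def test_matches_statsmodels_on_random_vectors(self, rng):
        for n in (10, 100, 1000):
            p = rng.uniform(size=n)
            assert np.allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1])


class TestDEFilters:
    def _frame(self, **overrides):
        row = {
            "baseMean": 50.0,
            **{f"log2FC_{t}": 0.0 for t in ("T2", "T3", "T4", "T5", "T6")},
            **{f"p_{t}": 1.0 for t in ("T2", "T3", "T4", "T5", "T6")},
            **{f"padj_{t}": 1.0 for t in ("T2", "T3", "T4", "T5", "T6")},
        }
        row.update(overrides)
        return pd.DataFrame([row], index=["feat"])

    def test_mirna_bounds_are_inclusive(self):
        res = apply_de_filters(
            self._frame(baseMean=10.0, log2FC_T6=-1.0, padj_T6=0.05), "mirna"
        )
        assert bool(res["de_any"].iloc[0])

    def test_mirna_just_below_lfc_bound_not_de(self):
        res = apply_de_filters(self._frame(log2FC_T6=-0.99, padj_T6=0.04), "mirna")
        assert not bool(res["de_any"].iloc[0])

    def test_mirna_below_basemean_floor_not_de(self):
        res = apply_de_filters(
            self._frame(baseMean=9.9, log2FC_T6=-2.0, padj_T6=0.001), "mirna"
        )
        assert not bool(res["de_any"].iloc[0])

    def test_mrna_threshold_inclusive(self):
        res = apply_de_filters(self._frame(log2FC_T4=0.80, p_T4=0.04), "mrna")
        assert bool(res["de_any"].iloc[0])

    def test_unknown_branch_rejected(self):
        with pytest.raises(ValueError):
            apply_de_filters(self._frame(), "protein")


def test_de_mirna_recovers_planted_features(small_dataset):
    ds = small_dataset
    res = de_mirna(ds.counts, ds.samples)
    planted = {m for v in ds.truth.de_mirnas.values() for m in v}
    called = set(res.index[res["de_any"]])
    assert len(called & planted) / len(planted) >= 0.9
    assert len(called - planted) / max(len(called), 1) <= 0.10
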