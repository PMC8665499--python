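"""Stability estimators against brute-force oracles and their invariants."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from refstab import (
    CtMatrix,
    StabilityAnalysis,
    bestkeeper,
    comprfinder,
    delta_ct_stability,
    genorm,
    normfinder,
)


def brute_force_m(values: pd.DataFrame) -> pd.Series:
    """Spreadsheet-style geNorm M: explicit loops over all gene pairs."""
    genes = list(values.index)
    q = {g: 2.0 ** (values.loc[g].min() - values.loc[g]) for g in genes}
    m = {}
    for j in genes:
        sds = []
        for k in genes:
            if k == j:
                continue
            ratios = np.log2(q[j].to_numpy() / q[k].to_numpy())
            sds.append(np.std(ratios, ddof=1))
        m[j] = np.mean(sds)
    return pd.Series(m)


def brute_force_delta_ct(values: pd.DataFrame) -> pd.Series:
    out = {}
    for j in values.index:
        sds = [np.std(values.loc[j] - values.loc[k], ddof=1)
               for k in values.index if k != j]
        out[j] = np.mean(sds)
    return pd.Series(out)


class TestGenorm:
    def test_m_matches_brute_force(self, toy_ct):
        res = genorm(toy_ct)
        expected = brute_force_m(toy_ct)
        pd.testing.assert_series_equal(
            res.initial_m, expected, check_names=False, atol=1e-12)

    def test_duplicate_genes_are_final_pair_with_zero_m(self, toy_ct):
        dup = toy_ct.copy()
        dup.loc["g2"] = dup.loc["g1"]
        res = genorm(dup)
        assert set(res.stability_order[:2]) == {"g1", "g2"}
        assert res.stepwise_m["g1"] == res.stepwise_m["g2"] == 0.0

    def test_per_sample_shift_invariance(self, toy_ct, rng):
        shifts = rng.normal(0, 2, size=toy_ct.shape[1])
        shifted = toy_ct + shifts[None, :]
        a, b = genorm(toy_ct), genorm(shifted)
        pd.testing.assert_series_equal(a.initial_m, b.initial_m, atol=1e-10)
        pd.testing.assert_series_equal(a.stepwise_m, b.stepwise_m, atol=1e-10)
        assert a.exclusion_order == b.exclusion_order
        pd.testing.assert_series_equal(
            a.pairwise_variation, b.pairwise_variation, atol=1e-10)

    def test_final_two_share_stepwise_m(self, rng):
        for _ in range(5):
            vals = pd.DataFrame(20 + rng.normal(0, 1, size=(6, 10)))
            res = genorm(vals)
            g1, g2 = res.stability_order[:2]
            assert res.stepwise_m[g1] == res.stepwise_m[g2]

    def test_initial_m_equals_delta_ct_at_efficiency_2(self, rng):
        vals = pd.DataFrame(18 + rng.normal(0, 1.5, size=(5, 8)))
        res = genorm(vals, efficiency=2.0)
        pd.testing.assert_series_equal(
            res.initial_m, delta_ct_stability(vals),
            check_names=False, atol=1e-12)

    def test_gene_and_sample_reordering_invariance(self, toy_ct, rng):
        perm_g = rng.permutation(toy_ct.index)
        perm_s = rng.permutation(toy_ct.columns)
        res_a = genorm(toy_ct)
        res_b = genorm(toy_ct.loc[perm_g, perm_s])
        pd.testing.assert_series_equal(
            res_a.initial_m.sort_index(), res_b.initial_m.sort_index(),
            atol=1e-12)

    def test_pairwise_variation_count(self, rng):
        vals = pd.DataFrame(20 + rng.normal(0, 1, size=(6, 12)))
        res = genorm(vals)
        assert list(res.pairwise_variation.index) == [
            "V2/3", "V3/4", "V4/5", "V5/6"]

    def test_ranks_are_permutation(self, toy_ct):
        res = genorm(toy_ct)
        assert sorted(res.ranks) == list(range(1, len(toy_ct) + 1))


class TestDeltaCt:
    def test_enumerated_pairs_toy_matrix(self):
        vals = pd.DataFrame(
            [[20.0, 21.0, 20.5, 22.0],
             [18.0, 18.5, 19.5, 19.0],
             [25.0, 26.5, 25.5, 27.0]],
            index=["a", "b", "c"])
        got = delta_ct_stability(vals)
        expected = brute_force_delta_ct(vals)
        pd.testing.assert_series_equal(got, expected, check_names=False,
                                       atol=1e-12)

    def test_duplicated_gene_shares_statistic(self, toy_ct):
        dup = pd.concat([toy_ct, toy_ct.loc[["g1"]].rename(index={"g1": "g1b"})])
        got = delta_ct_stability(dup)
        assert got["g1"] == pytest.approx(got["g1b"])

    def test_additive_shift_invariance(self, toy_ct, rng):
        shifted = toy_ct + rng.normal(0, 3, size=toy_ct.shape[1])[None, :]
        pd.testing.assert_series_equal(
            delta_ct_stability(toy_ct), delta_ct_stability(shifted), atol=1e-10)

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError):
            delta_ct_stability(pd.DataFrame([[20.0, 21.0]]))


class TestNormFinder:
    def test_single_group_ranking_equals_centered_variance(self, rng):
        vals = pd.DataFrame(20 + rng.normal(0, 1, size=(6, 30)),
                            index=[f"g{i}" for i in range(6)])
        got = normfinder(vals)
        z = vals - vals.mean(axis=0)
        var_rank = z.var(axis=1, ddof=1).rank()
        assert list(got.rank()) == list(var_rank)

    def test_constant_centered_gene_is_most_stable(self, rng):
        base = 20 + rng.normal(0, 1, size=(1, 40))  # shared sample offsets
        noise = rng.normal(0, 0.6, size=(5, 40))
        vals = np.vstack([base, base + noise])  # gene 0 = pure offset
        got = normfinder(pd.DataFrame(vals, index=[f"g{i}" for i in range(6)]))
        assert got.idxmin() == "g0"

    def test_group_shift_strictly_worsens_stability(self, rng):
        # two identical genes except one gets a +1 cycle shift in group B
        n = 10
        groups = ["A"] * n + ["B"] * n
        others = 20 + rng.normal(0, 0.4, size=(4, 2 * n))
        twin = 20 + rng.normal(0, 0.1, size=2 * n)
        shifted = twin.copy()
        shifted[n:] += 1.0
        vals = pd.DataFrame(np.vstack([twin, shifted, others]),
                            index=["twin", "shifted"] + [f"o{i}" for i in range(4)])
        got = normfinder(vals, groups)
        assert got["shifted"] > got["twin"]

    def test_singleton_group_excluded_with_warning(self, rng):
        vals = pd.DataFrame(20 + rng.normal(0, 0.5, size=(4, 7)))
        groups = ["A"] * 3 + ["B"] * 3 + ["C"]
        with pytest.warns(UserWarning, match="single sample"):
            got = normfinder(vals, groups)
        assert np.isfinite(got).all()


class TestBestKeeper:
    def test_mad_hand_computed(self):
        vals = pd.DataFrame([[20.0, 21.0, 19.0, 20.0],
                             [22.0, 22.0, 22.0, 22.0]], index=["a", "b"])
        out = bestkeeper(vals)
        assert out.loc["a", "bestkeeper_sd"] == pytest.approx(0.5)
        assert out.loc["a", "mean_ct"] == pytest.approx(20.0)
        assert out.loc["b", "bestkeeper_sd"] == 0.0
        assert out.loc["b", "cv_pct"] == 0.0

    def test_gene_equal_to_index_has_r_one(self, rng):
        a = 20 + rng.normal(0, 1, size=10)
        b = 24 + rng.normal(0, 1, size=10)
        idx = sps.gmean(np.vstack([a, b, np.sqrt(a * b)]), axis=0)
        # third gene is the geometric mean of the others -> index is a
        # monotone (power) function of it only up to noise; instead test
        # the exact identity: a gene numerically equal to the index
        vals = pd.DataFrame(np.vstack([a, b]), index=["a", "b"])
        out = bestkeeper(vals)
        index = out.attrs["index"].to_numpy()
        vals2 = pd.DataFrame(np.vstack([a, b, index]), index=["a", "b", "i"])
        out2 = bestkeeper(vals2)
        assert out2.loc["i", "r_vs_index"] == pytest.approx(1.0, abs=1e-6)

    def test_mad_never_exceeds_sample_sd(self, rng):
        vals = pd.DataFrame(20 + rng.normal(0, 1.5, size=(10, 25)))
        out = bestkeeper(vals)
        sd = vals.std(axis=1, ddof=1)
        assert (out["bestkeeper_sd"].to_numpy() <= sd.to_numpy() + 1e-12).all()

    def test_nonpositive_ct_rejected(self):
        with pytest.raises(ValueError):
            bestkeeper(pd.DataFrame([[20.0, -1.0], [20.0, 21.0]]))


class TestComprFinder:
    def test_hand_scaled_example(self):
        vals = pd.DataFrame({"m1": [1.0, 2.0, 3.0], "m2": [5.0, 9.0, 7.0]},
                            index=["a", "b", "c"])
        # scaled columns: {0, .5, 1} and {0, 1, .5} -> scores {0, .75, .75}
        out = comprfinder(vals)
        assert out.loc["a", "score"] == pytest.approx(0.0)
        assert out.loc["b", "score"] == pytest.approx(0.75)
        assert out.loc["c", "score"] == pytest.approx(0.75)
        # tie at 0.75: mean raw ranks are b=2.5, c=2.5 -> falls back to
        # input order, b before c
        assert out.loc["a", "rank"] == 1
        assert out.loc["b", "rank"] == 2
        assert out.loc["c", "rank"] == 3

    def test_unanimous_best_gene_scores_zero(self, rng):
        vals = pd.DataFrame(rng.uniform(1, 2, size=(5, 4)))
        vals.iloc[3] = 0.5  # best under every method
        out = comprfinder(vals)
        assert out.iloc[3]["score"] == 0.0
        assert out.iloc[3]["rank"] == 1

    def test_consensus_ordering_preserved(self):
        vals = pd.DataFrame({"m1": [1, 2, 3, 4], "m2": [10, 20, 30, 40.0]})
        out = comprfinder(vals)
        assert list(out["rank"]) == [1, 2, 3, 4]

    def test_affine_rescaling_invariance(self, rng):
        vals = pd.DataFrame(rng.uniform(0, 1, size=(6, 3)))
        out = comprfinder(vals)
        rescaled = vals * [3.0, 0.5, 100.0] + [1.0, -2.0, 7.0]
        out2 = comprfinder(rescaled)
        pd.testing.assert_frame_equal(out, out2)
        assert ((out["score"] >= 0) & (out["score"] <= 1)).all()

    def test_mismatched_gene_sets_rejected(self):
        vals = pd.DataFrame({"m1": [1.0, 2.0], "m2": [1.0, np.nan]})
        with pytest.raises(ValueError):
            comprfinder(vals)


class TestStabilityAnalysis:
    def test_fit_produces_consistent_tables(self, grouped_ct):
        res = StabilityAnalysis(grouped_ct).fit()
        tab = res.table()
        assert {"genorm_m", "normfinder", "bestkeeper_sd", "delta_ct_sd",
                "score", "final_rank"} <= set(tab.columns)
        for col in res.values.columns:
            assert sorted(res.ranks[col]) == list(range(1, grouped_ct.n_genes + 1))
        assert res.ranking[0] == res.comprehensive["rank"].idxmin()

    def test_method_subset_drops_column(self, grouped_ct):
        res = StabilityAnalysis(grouped_ct).fit(("genorm", "delta_ct"))
        assert list(res.values.columns) == ["genorm_m", "delta_ct_sd"]
        assert res.bestkeeper_table is None

    def test_report_serializable(self, grouped_ct):
        import json
        res = StabilityAnalysis(grouped_ct).fit()
        json.dumps(res.report())
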