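"""Normalization factors, relative expression, t-tests, concordance."""

import numpy as np
import pandas as pd
import pytest

from refstab import (
    NormalizerSet,
    NormalizerValidation,
    group_pairwise_ttests,
    normalization_factor,
    normalizer_concordance,
    relative_expression,
)


@pytest.fixture
def ct_frame(rng):
    genes = ["T", "R1", "R2", "R3"]
    vals = 20 + rng.normal(0, 1, size=(4, 12))
    return pd.DataFrame(vals, index=genes, columns=[f"s{i}" for i in range(12)])


class TestNormalizationFactor:
    def test_single_gene_identity(self, ct_frame):
        nf = normalization_factor(ct_frame, ["R1"])
        pd.testing.assert_series_equal(nf, ct_frame.loc["R1"],
                                       check_names=False)

    def test_two_gene_geometric_mean(self):
        vf = pd.DataFrame({"s": [20.0, 22.0]}, index=["R1", "R2"])
        nf = normalization_factor(vf, ["R1", "R2"])
        assert nf["s"] == pytest.approx(np.sqrt(20 * 22))

    def test_equal_cts_collapse(self):
        vf = pd.DataFrame({"s": [21.0, 21.0, 21.0]}, index=list("abc"))
        assert normalization_factor(vf, list("abc"))["s"] == pytest.approx(21.0)

    def test_missing_gene_and_bad_size(self, ct_frame):
        with pytest.raises(KeyError):
            normalization_factor(ct_frame, ["nope"])
        with pytest.raises(ValueError):
            NormalizerSet(())
        with pytest.raises(ValueError):
            NormalizerSet(tuple("abcdef"))


class TestRelativeExpression:
    def test_target_equal_to_nf_gives_one(self):
        vf = pd.DataFrame([[20.0, 21.0], [20.0, 21.0]], index=["T", "R"])
        rel = relative_expression(vf, "T", ["R"])
        assert np.allclose(rel, 1.0)

    def test_one_cycle_above_halves(self):
        vf = pd.DataFrame([[21.0], [20.0]], index=["T", "R"])
        assert relative_expression(vf, "T", ["R"]).iloc[0] == pytest.approx(0.5)

    def test_two_sample_evaluation(self):
        vf = pd.DataFrame([[18.0, 20.0], [20.0, 20.0]], index=["T", "R"])
        rel = relative_expression(vf, "T", ["R"])
        assert list(rel) == pytest.approx([4.0, 1.0])

    def test_target_in_normalizer_refused(self, ct_frame):
        with pytest.raises(ValueError, match="own normalizer"):
            relative_expression(ct_frame, "T", ["T", "R1"])

    def test_redundant_rg_at_nf_leaves_expression(self, ct_frame):
        """Adding an RG whose Ct equals the current NF changes nothing."""
        nf = normalization_factor(ct_frame, ["R1", "R2"])
        vf = pd.concat([ct_frame, nf.rename("R4").to_frame().T])
        a = relative_expression(vf, "T", ["R1", "R2"])
        b = relative_expression(vf, "T", ["R1", "R2", "R4"])
        pd.testing.assert_series_equal(a, b, atol=1e-10)


class TestPairwiseTTests:
    def test_identical_groups_give_p_one(self):
        vals = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        out = group_pairwise_ttests(vals, ["A"] * 3 + ["B"] * 3)
        assert out["p_matrix"].loc["A", "B"] == pytest.approx(1.0)

    def test_separated_groups_give_tiny_p(self, rng):
        vals = pd.Series(np.r_[1 + rng.normal(0, 1e-3, 3),
                               2 + rng.normal(0, 1e-3, 3)])
        out = group_pairwise_ttests(vals, ["A"] * 3 + ["B"] * 3)
        assert out["p_matrix"].loc["A", "B"] < 1e-6

    def test_eleven_groups_yield_55_pairs(self, rng):
        vals = pd.Series(rng.normal(0, 1, size=66))
        groups = np.repeat([f"G{i}" for i in range(11)], 6)
        out = group_pairwise_ttests(vals, groups)
        p = out["p_matrix"]
        assert p.shape == (11, 11)
        iu = np.triu_indices(11, k=1)
        assert len(p.to_numpy()[iu]) == 55
        assert np.allclose(p.to_numpy(), p.to_numpy().T)
        assert np.allclose(np.diag(p.to_numpy()), 1.0)

    def test_degenerate_equal_constant_groups_flagged(self):
        vals = pd.Series([2.0] * 4)
        out = group_pairwise_ttests(vals, ["A", "A", "B", "B"])
        assert out["degenerate_pairs"] == [("A", "B")]
        assert out["p_matrix"].loc["A", "B"] == 1.0

    def test_group_relabeling_equivariance(self, rng):
        vals = pd.Series(rng.normal(0, 1, size=12))
        groups = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        out = group_pairwise_ttests(vals, groups)
        relabel = {"A": "Z", "B": "Y", "C": "X"}
        out2 = group_pairwise_ttests(vals, [relabel[g] for g in groups])
        for a, b in [("A", "B"), ("A", "C"), ("B", "C")]:
            assert out["p_matrix"].loc[a, b] == pytest.approx(
                out2["p_matrix"].loc[relabel[a], relabel[b]])

    def test_bh_adjustment_monotone(self, rng):
        vals = pd.Series(rng.normal(0, 1, size=20))
        groups = np.repeat(list("ABCDE"), 4)
        out = group_pairwise_ttests(vals, groups, adjust="bh")
        raw = out["p_matrix"].to_numpy()
        adj = out["p_matrix_adjusted"].to_numpy()
        iu = np.triu_indices(5, k=1)
        assert (adj[iu] >= raw[iu] - 1e-12).all()


class TestConcordance:
    def test_self_concordance(self, rng):
        v = rng.uniform(0.1, 3.0, size=20)
        r, r2, p = normalizer_concordance(v, v)
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        v = rng.normal(0, 1, size=15)
        r, _, _ = normalizer_concordance(v, 2 * v + 3)
        assert r == pytest.approx(1.0)

    def test_textbook_pearson(self, rng):
        x = rng.normal(0, 1, size=10)
        y = rng.normal(0, 1, size=10)
        r, r2, _ = normalizer_concordance(x, y)
        cov = ((x - x.mean()) * (y - y.mean())).sum() / 9
        expected = cov / (x.std(ddof=1) * y.std(ddof=1))
        assert r == pytest.approx(expected)
        assert r2 == pytest.approx(expected**2)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError, match="zero variance"):
            normalizer_concordance([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            normalizer_concordance([1, 2], [1, 2, 3])


class TestNormalizerValidation:
    @pytest.fixture
    def fitted(self, rng):
        genes = ["T1", "T2", "R1", "R2", "R3", "ACTB"]
        vals = 20 + rng.normal(0, 0.8, size=(6, 18))
        vals[5] += np.repeat(rng.normal(0, 1.5, size=3), 6)  # unstable RG
        vf = pd.DataFrame(vals, index=genes,
                          columns=[f"s{i}" for i in range(18)])
        groups = np.repeat(["A", "B", "C"], 6)
        sets = [NormalizerSet(("R1", "R2", "R3")), NormalizerSet(("R1",)),
                NormalizerSet(("ACTB",))]
        return NormalizerValidation(vf, ("T1", "T2"), sets, groups).fit()

    def test_result_shapes(self, fitted):
        assert len(fitted.relative) == 2 * 3
        tab = fitted.relative_table()
        assert len(tab) == 2 * 3 * 18
        assert (tab["value"] > 0).all()

    def test_concordance_matrices_well_formed(self, fitted):
        for t in ("T1", "T2"):
            for mat in (fitted.expression_concordance[t],
                        fitted.pvalue_concordance[t]):
                arr = mat.to_numpy()
                assert np.allclose(arr, arr.T)
                assert np.allclose(np.diag(arr), 1.0)
                assert (arr >= -1 - 1e-12).all() and (arr <= 1 + 1e-12).all()

    def test_report_serializable(self, fitted):
        import json
        json.dumps(fitted.report())
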