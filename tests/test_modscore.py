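"""Module scoring, region masks, DEG filter chain, z-scores, proportion test."""

import numpy as np
import pandas as pd
import pytest

import lesionmap as lm
from lesionmap import modscore
from lesionmap.config import AnalysisConfig


def _toy_data(n_genes=120, n_units=30, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.gamma(2.0, 1.0, size=(n_genes, n_units)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"u{i}" for i in range(n_units)],
    )


class TestModuleScore:
    def test_constant_expression_scores_zero(self):
        data = pd.DataFrame(1.3, index=[f"g{i}" for i in range(60)],
                            columns=[f"u{i}" for i in range(10)])
        score = lm.module_score(data, ["g3", "g7"], seed=0)
        assert np.allclose(score, 0.0)

    def test_whole_genome_set_scores_zero(self):
        data = _toy_data()
        score = lm.module_score(data, list(data.index), seed=0)
        assert np.allclose(score, 0.0, atol=1e-12)

    def test_deterministic_given_seed(self):
        data = _toy_data()
        s1 = lm.module_score(data, ["g1", "g2", "g3"], seed=5)
        s2 = lm.module_score(data, ["g1", "g2", "g3"], seed=5)
        pd.testing.assert_series_equal(s1, s2)

    def test_invariant_under_global_shift(self):
        data = _toy_data()
        genes = ["g10", "g20", "g30"]
        s1 = lm.module_score(data, genes, seed=2)
        s2 = lm.module_score(data + 0.7, genes, seed=2)
        assert np.allclose(s1, s2, atol=1e-12)

    def test_null_sets_center_on_zero(self):
        data = modscore.log_normalize(_toy_data(400, 200, seed=1))
        rng = np.random.default_rng(3)
        means = []
        for i in range(40):
            genes = list(rng.choice(data.index, size=20, replace=False))
            means.append(lm.module_score(data, genes, seed=i).mean())
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means)) < 3 * se + 1e-3

    def test_empty_and_missing_sets_rejected(self):
        data = _toy_data()
        with pytest.raises(ValueError):
            lm.module_score(data, [], seed=0)
        with pytest.raises(KeyError):
            lm.module_score(data, ["nope"], seed=0)


class TestRegionMasks:
    def test_all_below_thresholds_gives_empty_masks(self):
        idx = pd.Index(["a", "b"])
        gm, les = lm.derive_region_masks(pd.Series([0.0, -1.0], index=idx),
                                         pd.Series([0.05, 0.0], index=idx))
        assert not gm.any() and not les.any()

    def test_membership_follows_each_threshold(self):
        idx = pd.Index(["s"])
        gm, les = lm.derive_region_masks(pd.Series([0.02], index=idx),
                                         pd.Series([0.05], index=idx))
        assert gm["s"] and not les["s"]

    def test_exact_threshold_excluded(self):
        idx = pd.Index(["s"])
        gm, les = lm.derive_region_masks(pd.Series([0.01], index=idx),
                                         pd.Series([0.1], index=idx))
        assert not gm["s"] and not les["s"]

    def test_misaligned_vectors_rejected(self):
        with pytest.raises(ValueError):
            lm.derive_region_masks(pd.Series([0.0], index=["a"]),
                                   pd.Series([0.0], index=["b"]))


def _nb_counts(mean, shape, rng, dispersion=8.0):
    lam = rng.gamma(dispersion, np.broadcast_to(mean, shape) / dispersion)
    return rng.poisson(lam)


class TestRankSumDEG:
    def test_null_keeps_almost_nothing(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(_nb_counts(2.0, (1000, 120), rng),
                              index=[f"g{i}" for i in range(1000)],
                              columns=[f"u{i}" for i in range(120)])
        labels = pd.Series(["A"] * 60 + ["B"] * 60, index=counts.columns)
        table = lm.rank_sum_deg(counts, labels, group1="A")
        assert table["kept"].sum() <= 2

    def test_planted_marker_is_kept(self):
        rng = np.random.default_rng(1)
        n1 = n2 = 200
        counts = pd.DataFrame(_nb_counts(0.05, (200, n1 + n2), rng),
                              index=[f"g{i}" for i in range(200)],
                              columns=[f"u{i}" for i in range(n1 + n2)])
        # plant one gene at 10x mean in group A only
        counts.iloc[0, :n1] = _nb_counts(2.0, (n1,), rng)
        labels = pd.Series(["A"] * n1 + ["B"] * n2, index=counts.columns)
        table = lm.rank_sum_deg(counts, labels, group1="A")
        assert table["kept"].iloc[0]

    def test_widely_detected_gene_filtered_by_pct2(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(_nb_counts(1.0, (50, 80), rng),
                              index=[f"g{i}" for i in range(50)],
                              columns=[f"u{i}" for i in range(80)])
        counts.iloc[0, :] = 5          # detected everywhere: pct.2 = 1
        counts.iloc[0, :40] = 500      # huge effect in group A regardless
        labels = pd.Series(["A"] * 40 + ["B"] * 40, index=counts.columns)
        table = lm.rank_sum_deg(counts, labels, group1="A")
        assert table["pct.2"].iloc[0] == 1.0
        assert not table["kept"].iloc[0]

    def test_adjusted_p_never_below_raw(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(_nb_counts(1.0, (100, 40), rng),
                              index=[f"g{i}" for i in range(100)],
                              columns=[f"u{i}" for i in range(40)])
        labels = pd.Series(["A"] * 20 + ["B"] * 20, index=counts.columns)
        table = lm.rank_sum_deg(counts, labels)
        assert (table["p_val_adj"] >= table["p_val"] - 1e-15).all()

    def test_small_group_rejected(self):
        counts = pd.DataFrame(np.ones((10, 5)), columns=list("abcde"))
        labels = pd.Series(["A", "A", "B", "B", "B"], index=counts.columns)
        with pytest.raises(ValueError):
            lm.rank_sum_deg(counts, labels)


class TestGroupZScores:
    def test_equal_group_means_give_zero(self):
        scores = pd.Series([1.0, 1.0, 1.0, 1.0], index=list("abcd"))
        labels = pd.Series(["x", "x", "y", "y"], index=scores.index)
        assert np.allclose(lm.zscore_group_scores(scores, labels), 0.0)

    def test_two_groups_give_plus_minus_sqrt_half(self):
        scores = pd.Series([0.0, 0.0, 2.0, 2.0], index=list("abcd"))
        labels = pd.Series(["lo", "lo", "hi", "hi"], index=scores.index)
        z = lm.zscore_group_scores(scores, labels)
        assert z["hi"] == pytest.approx(np.sqrt(2) / 2)
        assert z["lo"] == pytest.approx(-np.sqrt(2) / 2)

    def test_relabeling_permutes_z_identically(self):
        rng = np.random.default_rng(4)
        scores = pd.Series(rng.normal(size=30))
        labels = pd.Series(rng.choice(["a", "b", "c"], size=30), index=scores.index)
        z1 = lm.zscore_group_scores(scores, labels)
        swap = labels.map({"a": "b", "b": "a", "c": "c"})
        z2 = lm.zscore_group_scores(scores, swap)
        assert z1["a"] == pytest.approx(z2["b"])
        assert z1["c"] == pytest.approx(z2["c"])

    def test_single_group_rejected(self):
        scores = pd.Series([1.0, 2.0])
        with pytest.raises(ValueError):
            lm.zscore_group_scores(scores, pd.Series(["x", "x"]))


class TestProportionTest:
    def test_identical_composition_nothing_significant(self):
        clusters = pd.Series(list("ABCD") * 250)
        conditions = pd.Series(["ctrl"] * 500 + ["eae"] * 500)
        out = lm.proportion_permutation_test(clusters, conditions, n_perm=200, seed=0)
        assert not out["significant"].any()

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(5)
        ctrl = rng.choice(list("ABCD"), size=2000, p=[0.05, 0.35, 0.3, 0.3])
        eae = rng.choice(list("ABCD"), size=2000, p=[0.20, 0.30, 0.25, 0.25])
        clusters = pd.Series(np.concatenate([ctrl, eae]))
        conditions = pd.Series(["ctrl"] * 2000 + ["eae"] * 2000)
        out = lm.proportion_permutation_test(clusters, conditions, n_perm=1000, seed=1)
        assert out.loc["A", "significant"]

    def test_log2fc_antisymmetric_under_condition_swap(self):
        rng = np.random.default_rng(6)
        clusters = pd.Series(rng.choice(list("ABC"), size=600))
        conditions = pd.Series(["x"] * 300 + ["y"] * 300)
        fwd = lm.proportion_permutation_test(clusters, conditions, n_perm=100, seed=2)
        swapped = conditions.map({"x": "y", "y": "x"})
        rev = lm.proportion_permutation_test(clusters, swapped, n_perm=100, seed=2)
        assert np.allclose(fwd["log2FC"], -rev["log2FC"])

    def test_too_few_permutations_rejected(self):
        clusters = pd.Series(list("AB") * 10)
        conditions = pd.Series(["x", "y"] * 10)
        with pytest.raises(ValueError):
            lm.proportion_permutation_test(clusters, conditions, n_perm=10)


def test_log_normalize_fixed_totals():
    counts = pd.DataFrame([[10, 0], [30, 0]], index=["g1", "g2"], columns=["a", "b"])
    data = modscore.log_normalize(counts, scale_total=100)
    assert np.expm1(data["a"]).sum() == pytest.approx(100)
    assert (data["b"] == 0).all()
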