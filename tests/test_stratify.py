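"""ISM scoring, high/low classification, prevalence and group tests."""

import numpy as np
import pandas as pd
import pytest

from chromins.setscore import normalize_sc
from chromins.stratify import (
    ISMStratifier,
    chisq_test,
    classify_high_low,
    groupwise_wilcoxon,
    ism_score,
    map_groups,
    prevalence_table,
)
from chromins.synthetic import gen_sc, rast_sc_config

from conftest import oracle_permutation_ranksum_p


def expr_frame(arr, genes):
    return pd.DataFrame(
        np.asarray(arr, float), index=genes,
        columns=[f"c{j}" for j in range(np.asarray(arr).shape[1])],
    )


class TestIsmScore:
    def test_equal_genes_give_that_value(self):
        e = expr_frame([[2.0], [2.0], [2.0], [2.0]],
                       ["INSR", "IGF1R", "IRS1", "IRS2"])
        assert ism_score(e).iloc[0] == pytest.approx(2.0)

    def test_absent_gene_dropped_with_warning(self):
        e = expr_frame([[3.0], [6.0], [9.0]], ["INSR", "IGF1R", "IRS1"])
        with pytest.warns(UserWarning, match="IRS2"):
            s = ism_score(e)
        assert s.iloc[0] == pytest.approx(6.0)

    def test_all_genes_absent_errors(self):
        e = expr_frame([[1.0]], ["other"])
        with pytest.raises(ValueError):
            ism_score(e)


class TestClassifyHighLow:
    def test_global_mean_threshold(self):
        s = pd.Series([0.0, 0.0, 3.0], index=list("abc"))
        assert list(classify_high_low(s)) == ["low", "low", "high"]

    def test_all_equal_all_low(self):
        s = pd.Series([1.0, 1.0, 1.0])
        assert list(classify_high_low(s)) == ["low"] * 3

    def test_per_cluster_splits_at_own_mean(self):
        s = pd.Series([0.0, 1.0, 10.0, 11.0], index=list("abcd"))
        cl = pd.Series(["x", "x", "y", "y"], index=list("abcd"))
        labels = classify_high_low(s, scope="per-cluster", clusters=cl)
        assert list(labels) == ["low", "high", "low", "high"]
        # global scope instead splits between the clusters
        assert list(classify_high_low(s)) == ["low", "low", "high", "high"]

    def test_singleton_cluster_low_with_warning(self):
        s = pd.Series([5.0, 1.0, 2.0], index=list("abc"))
        cl = pd.Series(["solo", "y", "y"], index=list("abc"))
        with pytest.warns(UserWarning, match="singleton"):
            labels = classify_high_low(s, scope="per-cluster", clusters=cl)
        assert labels.loc["a"] == "low"


class TestPrevalence:
    def test_paper_style_contrast_arithmetic(self):
        labels = pd.Series(["high"] * 40 + ["low"] * 260 +
                           ["high"] * 20 + ["low"] * 280)
        groups = pd.Series(["aggressive"] * 300 + ["other"] * 300)
        res = prevalence_table(labels, groups)
        assert res.prevalence["aggressive"] == pytest.approx(13.3333, abs=1e-3)
        assert res.prevalence["other"] == pytest.approx(6.6667, abs=1e-3)
        assert res.n_cells == 600

    def test_all_low_gives_zero_prevalence(self):
        labels = pd.Series(["low"] * 10)
        groups = pd.Series(["a"] * 5 + ["b"] * 5)
        res = prevalence_table(labels, groups)
        assert (res.prevalence == 0).all()

    def test_counts_conserved(self, rng):
        n = 500
        labels = pd.Series(rng.choice(["high", "low"], size=n))
        groups = pd.Series(rng.choice(["a", "b"], size=n))
        assert prevalence_table(labels, groups).n_cells == n

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            prevalence_table(pd.Series(["high", "low"]), pd.Series(["a", "a"]))


class TestChiSquare:
    def test_frozen_two_by_two(self):
        # Sum (O-E)^2/E with margins 300/300 and 60/540: 7.4074
        res = chisq_test(np.array([[40, 20], [260, 280]]))
        assert res.statistic == pytest.approx(7.4074, abs=1e-3)
        assert res.p == pytest.approx(0.00650, abs=2e-4)
        assert res.df == 1

    def test_proportional_table_statistic_zero(self):
        res = chisq_test(np.array([[30, 60], [70, 140]]))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_equals_brute_force_identity(self, rng):
        for _ in range(50):
            t = rng.integers(1, 200, size=(2, 2)).astype(float)
            row, col = t.sum(1), t.sum(0)
            E = np.outer(row, col) / t.sum()
            assert chisq_test(t).statistic == pytest.approx(
                float(((t - E) ** 2 / E).sum())
            )

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chisq_test(np.array([[0, 0], [5, 5]]))


class TestWilcoxon:
    def test_identical_groups_large_p(self):
        v = pd.Series(list(range(10)) * 2, dtype=float)
        lab = pd.Series(["a"] * 10 + ["b"] * 10)
        assert groupwise_wilcoxon(v, lab).p >= 0.9

    def test_complete_separation_small_p(self, rng):
        v = pd.Series(np.concatenate([rng.normal(0, 1, 10),
                                      rng.normal(20, 1, 10)]))
        lab = pd.Series(["a"] * 10 + ["b"] * 10)
        assert groupwise_wilcoxon(v, lab).p < 0.001

    def test_matches_exhaustive_permutation_oracle(self, rng):
        for _ in range(12):
            n1 = int(rng.integers(3, 8))
            n2 = int(rng.integers(3, 8))
            a = rng.normal(size=n1)
            b = rng.normal(0.8, 1.0, size=n2)
            v = pd.Series(np.concatenate([a, b]))
            lab = pd.Series(["a"] * n1 + ["b"] * n2)
            p = groupwise_wilcoxon(v, lab).p
            assert p == pytest.approx(oracle_permutation_ranksum_p(a, b),
                                      abs=0.01)

    def test_paired_all_zero_differences(self):
        v = pd.Series([1.0, 2, 3, 4, 5] * 2)
        lab = pd.Series(["a"] * 5 + ["b"] * 5)
        with pytest.warns(UserWarning, match="zero"):
            res = groupwise_wilcoxon(v, lab, paired=True)
        assert res.p == 1.0

    def test_paired_detects_shift(self, rng):
        base = rng.normal(size=12)
        v = pd.Series(np.concatenate([base, base + 2.0]))
        lab = pd.Series(["a"] * 12 + ["b"] * 12)
        assert groupwise_wilcoxon(v, lab, paired=True).p < 0.01

    def test_group_size_preconditions(self):
        with pytest.raises(ValueError):
            groupwise_wilcoxon(pd.Series([1.0, 2, 3, 4]),
                               pd.Series(["a", "a", "b", "b"]))


class TestMapGroups:
    def test_default_aggressive_mapping_total(self):
        cl = pd.Series(["Tph", "naive", "Vdelta2", "weird"])
        g = map_groups(cl)
        assert list(g) == ["aggressive", "other", "aggressive", "other"]


class TestStratifierOnSynthetic:
    def test_score_separates_planted_classes(self):
        counts, meta, truth = gen_sc(rast_sc_config(n_cells=1500), 42)
        expr = normalize_sc(counts)
        scores = ism_score(expr)
        hi = scores[truth["true_high"]]
        lo = scores[~truth["true_high"]]
        # AUC by rank comparison
        from scipy.stats import mannwhitneyu

        u = mannwhitneyu(hi, lo).statistic
        auc = u / (len(hi) * len(lo))
        assert auc > 0.9

    def test_labels_agree_with_truth_at_stated_shift(self):
        counts, meta, truth = gen_sc(rast_sc_config(n_cells=1500), 43)
        strat = ISMStratifier().fit(normalize_sc(counts), meta)
        agree = (strat.labels_.eq("high") == truth["true_high"]).mean()
        assert agree > 0.9

    def test_scope_behaviour_with_cluster_level_differences(self):
        # no planted cells; clusters differ only in baseline ISM level
        cfg = rast_sc_config(
            n_cells=1200,
            prevalence={"aggressive": 0.0, "other": 0.0},
            cluster_ism_scale={"Tph": 2.0, "proliferating": 2.0,
                               "Vdelta2": 2.0},
        )
        counts, meta, _ = gen_sc(cfg, 44)
        expr = normalize_sc(counts)
        scores = ism_score(expr)
        glob = classify_high_low(scores, scope="global")
        prev_g = prevalence_table(glob, meta["group"]).prevalence
        # global split tracks the cluster-level difference
        assert prev_g["aggressive"] > 90 and prev_g["other"] < 10
        per = classify_high_low(scores, scope="per-cluster",
                                clusters=meta["cluster"])
        prev_c = prevalence_table(per, meta["group"]).prevalence
        # per-cluster split lands near 50% everywhere
        assert abs(prev_c["aggressive"] - 50) < 10
        assert abs(prev_c["other"] - 50) < 10
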