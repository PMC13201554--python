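"""Gene-set scores, mean splits, correlations, expression ratios, ORA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chromins.setscore import (
    GeneSet,
    SESScorer,
    expression_ratio,
    normalize_sc,
    ora,
    read_gmt,
    ses,
    spearman,
    split_by_gene_mean,
    write_gmt,
)

from conftest import oracle_hypergeom_upper_tail, oracle_spearman_rho


def expr_frame(arr, genes=None):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=genes or [f"g{i}" for i in range(arr.shape[0])],
        columns=[f"u{j}" for j in range(arr.shape[1])],
    )


class TestGmt:
    def test_basic_line_parsed(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("glyco\tGO:0006096\tHK1\tPFKM\n")
        sets = read_gmt(p)
        assert sets[0].members == ("HK1", "PFKM")
        assert sets[0].source == "GO:0006096"

    def test_duplicate_member_collapsed_with_warning(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("s1\tdesc\tA\tA\n")
        with pytest.warns(UserWarning, match="duplicate"):
            sets = read_gmt(p)
        assert sets[0].members == ("A",)

    def test_short_line_is_parse_error(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("only\ttwo\n")
        with pytest.raises(ValueError, match="< 3 fields"):
            read_gmt(p)

    def test_empty_file_gives_empty_collection(self, tmp_path):
        p = tmp_path / "e.gmt"
        p.write_text("")
        assert read_gmt(p) == []

    def test_roundtrip(self, tmp_path):
        sets = [GeneSet("a", "SRC:1", ("x", "y")), GeneSet("b", "SRC:2", ("z",))]
        write_gmt(sets, tmp_path / "w.gmt")
        assert read_gmt(tmp_path / "w.gmt") == sets


class TestSES:
    def test_one_gene_two_units_worked_example(self):
        e = expr_frame([[0.0, 2.0]])
        scores, n_used = ses(e, GeneSet("s", "", ("g0",)))
        assert n_used == 1
        assert np.allclose(scores.values, [-0.7071, 0.7071], atol=1e-4)

    def test_scores_sum_to_zero(self, rng):
        e = expr_frame(rng.normal(5, 2, size=(30, 12)))
        gs = GeneSet("s", "", tuple(f"g{i}" for i in range(0, 30, 3)))
        scores, n_used = ses(e, gs)
        assert abs(scores.sum()) < 1e-8 * e.shape[1]
        assert n_used == 10

    @given(st.floats(0.1, 50.0), st.floats(-100.0, 100.0))
    @settings(max_examples=20, deadline=None)
    def test_invariant_under_positive_affine_transform(self, a, b):
        rng = np.random.default_rng(7)
        e = expr_frame(rng.normal(size=(8, 6)))
        gs = GeneSet("s", "", tuple(f"g{i}" for i in range(8)))
        base, _ = ses(e, gs)
        trans, _ = ses(a * e + b, gs)
        assert np.allclose(base.values, trans.values, atol=1e-8)

    def test_absent_and_flat_genes_dropped(self):
        e = expr_frame([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]])
        gs = GeneSet("s", "", ("g0", "g1", "missing"))
        scores, n_used = ses(e, gs)
        assert n_used == 1  # only g1 varies
        assert np.isfinite(scores).all()

    def test_no_usable_gene_scores_missing(self):
        e = expr_frame([[2.0, 2.0]])
        with pytest.warns(UserWarning, match="no usable"):
            scores, n_used = ses(e, GeneSet("s", "", ("g0",)))
        assert n_used == 0 and scores.isna().all()

    def test_unit_permutation_permutes_scores(self, rng):
        e = expr_frame(rng.normal(size=(10, 8)))
        gs = GeneSet("s", "", tuple(f"g{i}" for i in range(10)))
        base, _ = ses(e, gs)
        perm = list(rng.permutation(e.columns))
        permuted, _ = ses(e[perm], gs)
        assert np.allclose(permuted.values, base.loc[perm].values)

    def test_scorer_transform_shape_and_accounting(self, rng):
        e = expr_frame(rng.normal(size=(12, 5)))
        sets = [GeneSet("a", "", ("g0", "g1")), GeneSet("b", "", ("g2",))]
        scorer = SESScorer(sets)
        out = scorer.fit(e).transform(e)
        assert out.shape == (5, 2)
        assert scorer.n_genes_used_.to_dict() == {"a": 2, "b": 1}


class TestSplitByGeneMean:
    def test_values_above_mean_are_hi(self):
        e = expr_frame([[1.0, 1.0, 4.0]])
        assert list(split_by_gene_mean(e, "g0")) == ["lo", "lo", "hi"]

    def test_constant_gene_all_lo(self):
        e = expr_frame([[3.0, 3.0, 3.0]])
        assert list(split_by_gene_mean(e, "g0")) == ["lo", "lo", "lo"]

    def test_two_units(self):
        e = expr_frame([[0.0, 10.0]])
        assert list(split_by_gene_mean(e, "g0")) == ["lo", "hi"]

    def test_absent_gene_errors(self):
        with pytest.raises(KeyError):
            split_by_gene_mean(expr_frame([[1, 2]]), "nope")


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1.0, 2.0, 3.0, 5.0]
        assert spearman(x, x).rho == pytest.approx(1.0)
        assert spearman(x, [-v for v in x]).rho == pytest.approx(-1.0)

    def test_hand_rank_example(self):
        res = spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.rho == pytest.approx(0.8)

    def test_constant_vector_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            res = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(res.rho)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2, 3])

    def test_matches_rank_then_pearson_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 30))
            x = rng.integers(0, 8, size=n).astype(float)  # ties likely
            y = rng.normal(size=n)
            if np.ptp(x) == 0:
                continue
            assert spearman(x, y).rho == pytest.approx(
                oracle_spearman_rho(x, y), abs=1e-12
            )


class TestExpressionRatio:
    def test_equal_genes_ratio_one(self):
        e = expr_frame([[3.0, 8.0], [3.0, 8.0]])
        assert np.allclose(expression_ratio(e, "g0", "g1"), 1.0)

    def test_pseudocount_arithmetic(self):
        e = expr_frame([[3.0], [1.0]])
        assert expression_ratio(e, "g0", "g1").iloc[0] == pytest.approx(2.0)

    def test_zero_denominator_finite(self):
        e = expr_frame([[5.0], [0.0]])
        assert np.isfinite(expression_ratio(e, "g0", "g1")).all()

    def test_absent_gene_errors(self):
        with pytest.raises(KeyError):
            expression_ratio(expr_frame([[1.0]]), "g0", "nope")


class TestOra:
    def test_full_overlap_closed_form(self):
        universe = [f"u{i}" for i in range(20)]
        query = universe[:5]
        sets = [GeneSet("s", "", tuple(universe[:5]))]
        out = ora(query, sets, universe)
        assert out.loc[0, "p"] == pytest.approx(1 / 15504, rel=1e-9)

    def test_no_overlap_p_near_one(self):
        universe = [f"u{i}" for i in range(30)]
        sets = [GeneSet("s", "", tuple(universe[:2]))]
        out = ora(universe[10:12], sets, universe)
        assert out.loc[0, "p"] > 0.5
        assert out.loc[0, "overlap"] == 0

    def test_matches_exact_tail_enumeration(self, rng):
        for _ in range(100):
            M = int(rng.integers(5, 31))
            universe = [f"u{i}" for i in range(M)]
            K = int(rng.integers(1, M + 1))
            n = int(rng.integers(1, M + 1))
            members = list(rng.choice(universe, size=K, replace=False))
            query = list(rng.choice(universe, size=n, replace=False))
            out = ora(query, [GeneSet("s", "", tuple(members))], universe)
            k = int(out.loc[0, "overlap"])
            assert out.loc[0, "p"] == pytest.approx(
                oracle_hypergeom_upper_tail(k, M, K, n), rel=1e-9
            )

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            ora({"z"}, [GeneSet("s", "", ("a",))], {"a", "b"})


class TestNormalizeSc:
    def test_cells_scaled_to_median_depth(self, rng):
        counts = pd.DataFrame(rng.poisson(20, size=(30, 11)))
        counts.index = [f"g{i}" for i in range(30)]
        counts.columns = [f"c{j}" for j in range(11)]
        e = normalize_sc(counts)
        lin = (2.0 ** e) - 1.0
        totals = lin.sum(axis=0)
        assert np.allclose(totals, np.median(counts.sum(axis=0)), rtol=1e-6)
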