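"""Differential-expression engine: size factors, BH, NB Wald fits."""

import numpy as np
import pandas as pd
import pytest

from chromins.diffexpr import (
    _irls_batch,
    bh_adjust,
    insulin_responsive,
    nb_fit,
    read_counts_mtx,
    size_factors,
    write_counts_mtx,
)
from chromins.synthetic import BulkSimConfig, gen_bulk

from conftest import oracle_bh


def _counts(arr, units=None):
    arr = np.asarray(arr)
    return pd.DataFrame(
        arr,
        index=[f"g{i}" for i in range(arr.shape[0])],
        columns=units or [f"u{j}" for j in range(arr.shape[1])],
    )


class TestSizeFactors:
    def test_doubled_unit_recovers_sqrt2_pair(self):
        c = _counts([[10, 20], [100, 200], [3, 6]])
        sf = size_factors(c)
        assert np.allclose(sf.values, [1 / np.sqrt(2), np.sqrt(2)])

    def test_identical_units_give_ones(self):
        c = _counts([[5, 5, 5], [9, 9, 9]])
        assert np.allclose(size_factors(c).values, 1.0)

    def test_single_gene_closed_form(self):
        c = _counts([[4, 16]])
        assert np.allclose(size_factors(c).values, [0.5, 2.0])

    def test_geometric_mean_is_one(self, rng):
        c = _counts(rng.poisson(50, size=(40, 6)) + 1)
        sf = size_factors(c)
        assert np.isclose(np.exp(np.mean(np.log(sf))), 1.0)

    def test_no_common_gene_requires_fallback(self):
        c = _counts([[5, 0], [0, 7]])
        with pytest.raises(ValueError, match="pseudo_reference"):
            size_factors(c)
        sf = size_factors(c, pseudo_reference=True)
        assert (sf > 0).all()


class TestBHAdjust:
    def test_hand_worked_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_singleton_passthrough(self):
        assert bh_adjust([1.0]) == pytest.approx([1.0])

    def test_monotone_on_sorted_input(self, rng):
        p = np.sort(rng.random(50))
        adj = bh_adjust(p)
        assert (np.diff(adj) >= -1e-12).all()

    def test_nan_passthrough_excluded_from_m(self):
        adj = bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(adj[1])
        # m=2, not 3
        assert adj[0] == pytest.approx(0.02)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(100):
            p = rng.random(int(rng.integers(1, 40)))
            assert np.allclose(bh_adjust(p), oracle_bh(p))


class TestIRLSEngine:
    def test_matches_statsmodels_fixed_dispersion(self, rng):
        import statsmodels.api as sm

        n = 16
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        offset = rng.normal(0, 0.2, size=n)
        phi = 0.15
        mu = np.exp(1.8 + 0.7 * X[:, 1] + offset)
        Y = rng.negative_binomial(1 / phi, 1 / (1 + phi * mu),
                                  size=(12, n)).astype(float)
        Y = np.maximum(Y, 0) + 0.0
        beta, cov, conv = _irls_batch(Y, X, offset,
                                      np.full(12, phi), max_iter=100)
        assert conv.all()
        for g in range(12):
            fit = sm.GLM(
                Y[g], X, family=sm.families.NegativeBinomial(alpha=phi),
                offset=offset,
            ).fit()
            assert np.allclose(beta[g], fit.params, atol=1e-5)
            assert np.allclose(np.sqrt(np.diag(cov[g])), fit.bse,
                               rtol=1e-4, atol=1e-6)

    def test_flat_gene_has_zero_estimate(self):
        counts = _counts(np.full((3, 8), 50))
        meta = pd.DataFrame(
            {"insulin": np.arange(8, dtype=float) + 1.0},
            index=counts.columns,
        )
        res = nb_fit(counts, meta, design="covariate")
        assert np.allclose(res["estimate_log2"], 0.0, atol=1e-6)

    def test_offsets_absorb_unit_scaling(self):
        # Normalisation enters only through the offsets: pre-dividing the
        # matrix by its size factors (factors then ~1) leaves the
        # estimates essentially unchanged.  Exact invariance is not a
        # property of a count likelihood (rescaling one observation
        # reweights the score equation), so the tolerance is approximate.
        cfg = BulkSimConfig(n_genes=300, n_samples=12, design="paired",
                            responsive_fraction=0.1)
        counts, meta, _ = gen_bulk(cfg, 5)
        base = nb_fit(counts, meta, design="paired-contrast")
        sf = size_factors(counts)
        normed = counts.astype(float).div(sf, axis=1)
        res = nb_fit(normed, meta, design="paired-contrast")
        d = (res["estimate_log2"] - base["estimate_log2"]).abs()
        assert float(d.median()) < 0.01
        assert float(d.max()) < 0.1

    def test_all_zero_gene_excluded_from_bh(self):
        cfg = BulkSimConfig(n_genes=60, n_samples=12, design="paired",
                            responsive_fraction=0.0)
        counts, meta, _ = gen_bulk(cfg, 3)
        counts.iloc[0] = 0
        res = nb_fit(counts, meta, design="paired-contrast")
        assert np.isnan(res.iloc[0]["p"]) and np.isnan(res.iloc[0]["padj"])
        assert res["p"].notna().sum() == 59

    def test_padj_never_below_p(self):
        cfg = BulkSimConfig(n_genes=200, n_samples=12, design="paired")
        counts, meta, _ = gen_bulk(cfg, 9)
        res = nb_fit(counts, meta, design="paired-contrast").dropna()
        assert (res["padj"] >= res["p"] - 1e-12).all()

    def test_planted_log2fc_recovered(self):
        cfg = BulkSimConfig(n_genes=2000, n_samples=12, design="paired",
                            responsive_fraction=0.1, log2fc=1.0)
        counts, meta, truth = gen_bulk(cfg, 17)
        res = nb_fit(counts, meta, design="paired-contrast")
        up = truth.index[truth["effect_log2"] > 0]
        med = float(res.loc[up, "estimate_log2"].median())
        assert abs(med - 1.0) < 0.15

    def test_metadata_validation(self):
        counts = _counts([[1, 2, 3, 4]])
        meta = pd.DataFrame({"group": ["a", "b", "a", "b"]},
                            index=["u0", "u1", "u2", "zz"])
        with pytest.raises(ValueError, match="missing units"):
            nb_fit(counts, meta, design="paired-contrast")


class TestMtxRoundtrip:
    def test_counts_roundtrip_via_mtx(self, tmp_path, rng):
        c = _counts(rng.poisson(4, size=(15, 6)))
        write_counts_mtx(c, tmp_path / "m.mtx", tmp_path / "g.txt",
                         tmp_path / "u.txt")
        back = read_counts_mtx(tmp_path / "m.mtx", tmp_path / "g.txt",
                               tmp_path / "u.txt")
        pd.testing.assert_frame_equal(back, c)


class TestInsulinResponsive:
    @staticmethod
    def _res(sig, allgenes):
        padj = pd.Series(
            [0.01 if g in sig else 0.5 for g in allgenes], index=allgenes
        )
        return pd.DataFrame({"padj": padj})

    def test_union_and_venn_counts(self):
        genes = list("abcd")
        resp = insulin_responsive(self._res({"a", "b"}, genes),
                                  self._res({"b", "c"}, genes))
        assert resp.genes == {"a", "b", "c"}
        assert resp.venn_counts() == {"stim_only": 1, "reg_only": 1,
                                      "both": 1, "union": 3}

    def test_alpha_zero_gives_empty_set(self):
        genes = list("ab")
        resp = insulin_responsive(self._res({"a"}, genes),
                                  self._res({"b"}, genes), alpha=0.0)
        assert resp.genes == set()

    def test_disjoint_universes_warn(self):
        with pytest.warns(UserWarning, match="disjoint"):
            insulin_responsive(self._res({"a"}, ["a"]),
                               self._res({"z"}, ["z"]))
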