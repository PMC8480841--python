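"""Burden tests, relationship matrices, REML heritability, variance explained."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg, stats

import ontogwas as og
from ontogwas.genetics import _merge_small_bins
from ontogwas.genotype import GeneMutationMatrix


def _genes(values, gene_ids):
    df = pd.DataFrame(values, columns=gene_ids,
                      index=[f"s{i}" for i in range(len(values))])
    return GeneMutationMatrix(df.astype(np.int8))


class TestBurdenTest:
    def test_three_group_anova_matches_hand_computation(self):
        # groups {1,2,3}, {2,3,4}, {7,8,9}: SSB = 62 (2 df), SSW = 6 (6 df)
        # so F = (62/2)/(6/6) = 31.0
        y = np.array([1, 2, 3, 2, 3, 4, 7, 8, 9], dtype=float)
        burden = np.repeat([0, 1, 2], 3)
        genes = _genes(np.column_stack([burden >= 1, burden >= 2,
                                        np.tile([0, 1, 0], 3),
                                        np.tile([1, 0, 0], 3),
                                        np.tile([0, 0, 1], 3)]),
                       ["A", "B", "C", "D", "E"])
        pheno = pd.Series(y, index=genes.values.index)
        res = og.burden_test(genes, ["A", "B"], pheno, n_random=20, seed=0,
                             min_group_size=2)
        assert res.anova_F == pytest.approx(31.0)
        assert res.anova_p == pytest.approx(
            stats.f.sf(31.0, 2, 6), rel=1e-10)
        scipy_F, scipy_p = stats.f_oneway(y[:3], y[3:6], y[6:])
        assert res.anova_F == pytest.approx(scipy_F)
        assert res.anova_p == pytest.approx(scipy_p)

    def test_planted_negative_effect_detected(self):
        rng = np.random.default_rng(1)
        n = 300
        system = [f"G{j}" for j in range(4)]
        others = [f"H{j}" for j in range(40)]
        vals = np.column_stack([
            rng.integers(0, 2, (n, len(system))),
            rng.integers(0, 2, (n, len(others))),
        ])
        genes = _genes(vals, system + others)
        burden = vals[:, :4].sum(axis=1)
        y = pd.Series(-1.0 * burden + 0.1 * rng.normal(size=n),
                      index=genes.values.index)
        res = og.burden_test(genes, system, y, n_random=100, seed=2)
        assert res.anova_p < 1e-6
        pair = res.tukey[(res.tukey.bin_a == "0") & (res.tukey.bin_b == "2")]
        assert (pair["p_adj"] < 0.01).all() and len(pair) == 1
        # burden lowers the phenotype monotonically across the first bins
        means = res.groups["mean_phenotype"].to_numpy()
        assert means[0] > means[1] > means[2]

    def test_null_calibration_within_binomial_interval(self):
        hits = 0
        n_runs = 200
        rng = np.random.default_rng(3)
        system = [f"G{j}" for j in range(3)]
        others = [f"H{j}" for j in range(30)]
        for _ in range(n_runs):
            vals = np.column_stack([rng.integers(0, 2, (120, 3)),
                                    rng.integers(0, 2, (120, 30))])
            genes = _genes(vals, system + others)
            y = pd.Series(rng.normal(size=120), index=genes.values.index)
            res = og.burden_test(genes, system, y, n_random=1, seed=0)
            hits += res.anova_p < 0.05
        lo = stats.binom.ppf(0.005, n_runs, 0.05)
        hi = stats.binom.ppf(0.995, n_runs, 0.05)
        assert lo <= hits <= hi

    def test_small_bins_merge_downward(self):
        burden = np.array([0] * 10 + [1] * 10 + [2] * 2)
        merged = _merge_small_bins(burden, 5)
        assert set(merged) == {0, 1}
        assert (merged[-2:] == 1).all()

    def test_non_informative_burden_error(self, rng):
        genes = _genes(np.ones((20, 2), dtype=int), ["A", "B"])
        y = pd.Series(rng.normal(size=20), index=genes.values.index)
        with pytest.raises(ValueError, match="non-informative"):
            og.burden_test(genes, ["A"], y, n_random=5)

    def test_null_distribution_shape(self, rng):
        vals = rng.integers(0, 2, (100, 30))
        genes = _genes(vals, [f"G{j:02d}" for j in range(30)])
        y = pd.Series(rng.normal(size=100), index=genes.values.index)
        res = og.burden_test(genes, ["G00", "G01"], y, n_random=50, seed=4)
        assert res.random_null.shape[0] == 50
        assert list(res.random_null.columns) == list(res.groups.index)


class TestGrm:
    def test_identical_strains_share_kinship(self):
        Z = pd.DataFrame([[1, 0, 1, 0, 1]] * 2 + [[0, 1, 0, 1, 0]],
                         index=["a", "b", "c"])
        K = og.additive_grm(Z)
        v = K.values
        assert v.loc["a", "b"] == pytest.approx(v.loc["a", "a"])
        assert v.loc["a", "b"] == pytest.approx(v.loc["b", "b"])

    def test_mean_diagonal_near_one(self, rng):
        Z = pd.DataFrame(rng.integers(0, 2, (40, 600)))
        K = og.additive_grm(Z)
        assert np.mean(np.diag(K.values)) == pytest.approx(1.0, abs=0.1)

    def test_entries_match_bruteforce(self, rng):
        Z = pd.DataFrame(rng.integers(0, 2, (5, 8)).astype(float))
        K = og.additive_grm(Z)
        Zv = Z.to_numpy()
        keep = Zv.std(axis=0) > 0
        Zs = (Zv[:, keep] - Zv[:, keep].mean(0)) / Zv[:, keep].std(0)
        m = keep.sum()
        for s in range(5):
            for t in range(5):
                expect = sum(Zs[s, j] * Zs[t, j] for j in range(m)) / m
                assert K.values.iloc[s, t] == pytest.approx(expect)

    def test_all_monomorphic_error(self):
        with pytest.raises(ValueError, match="monomorphic"):
            og.additive_grm(pd.DataFrame(np.ones((4, 3))))

    def test_epistatic_square_and_psd(self, rng):
        Z = pd.DataFrame(rng.integers(0, 2, (20, 100)))
        K = og.additive_grm(Z)
        E = og.epistatic_grm(K)
        assert np.allclose(E.values, K.values ** 2)
        assert og.epistatic_grm(
            og.Kinship(pd.DataFrame(np.eye(5)), "additive")
        ).values.equals(pd.DataFrame(np.eye(5)))
        for seed in range(20):
            r = np.random.default_rng(seed)
            A = r.normal(size=(10, 10))
            P = pd.DataFrame(A @ A.T / 10)
            E = og.epistatic_grm(og.Kinship(P, "additive"))
            assert linalg.eigvalsh(E.values.to_numpy()).min() > -1e-8


def _simulated_kinship(rng, n, m):
    Z = rng.binomial(1, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(float)
    return og.additive_grm(pd.DataFrame(Z, index=[f"s{i}" for i in range(n)]))


class TestHeritability:
    def test_null_trait_h2_near_zero(self):
        rng = np.random.default_rng(11)
        K = _simulated_kinship(rng, 200, 400)
        y = pd.Series(rng.normal(size=200), index=K.strains)
        est = og.estimate_variance_components(y, K, og.epistatic_grm(K))
        assert est.h2 <= 0.1

    def test_noiseless_additive_trait(self):
        rng = np.random.default_rng(12)
        K = _simulated_kinship(rng, 150, 300)
        L = np.linalg.cholesky(K.values.to_numpy() + 1e-8 * np.eye(150))
        y = pd.Series(L @ rng.normal(size=150), index=K.strains)
        est = og.estimate_variance_components(y, K)
        assert est.h2 >= 0.95

    def test_affine_invariance(self):
        rng = np.random.default_rng(13)
        K = _simulated_kinship(rng, 120, 250)
        L = np.linalg.cholesky(K.values.to_numpy() + 1e-8 * np.eye(120))
        y = pd.Series(L @ rng.normal(size=120) + rng.normal(size=120),
                      index=K.strains)
        a = og.estimate_variance_components(y, K)
        b = og.estimate_variance_components(100.0 - 7.0 * y, K)
        assert a.h2 == pytest.approx(b.h2, abs=1e-3)

    def test_constant_trait_error(self):
        rng = np.random.default_rng(14)
        K = _simulated_kinship(rng, 50, 100)
        with pytest.raises(ValueError, match="constant"):
            og.estimate_variance_components(
                pd.Series(np.ones(50), index=K.strains), K)

    def test_summary_reports_h2(self):
        est = og.genetics.HeritabilityEstimate(1.0, 0.5, 0.5)
        assert est.h2 == pytest.approx(0.5)
        assert "h2" in est.summary()


class TestVarianceExplained:
    def test_single_indicator_equals_squared_pearson(self, rng):
        vals = rng.integers(0, 2, (200, 5))
        genes = _genes(vals, [f"G{j}" for j in range(5)])
        y = pd.Series(vals[:, 2] * 2.0 + rng.normal(size=200),
                      index=genes.values.index)
        ve = og.variance_explained(genes, ["G2"], y)
        r = np.corrcoef(vals[:, 2], y)[0, 1]
        assert ve.r2 == pytest.approx(r ** 2, abs=1e-10)

    def test_monotone_under_gene_set_growth(self, rng):
        vals = rng.integers(0, 2, (150, 10))
        genes = _genes(vals, [f"G{j}" for j in range(10)])
        y = pd.Series(rng.normal(size=150), index=genes.values.index)
        r2s = [og.variance_explained(genes, [f"G{j}" for j in range(k)], y).r2
               for k in range(1, 8)]
        assert all(b >= a - 1e-12 for a, b in zip(r2s, r2s[1:]))

    def test_null_gene_set_explains_little(self):
        rng = np.random.default_rng(15)
        vals = rng.integers(0, 2, (1000, 6))
        genes = _genes(vals, [f"G{j}" for j in range(6)])
        y = pd.Series(rng.normal(size=1000), index=genes.values.index)
        assert og.variance_explained(genes, [f"G{j}" for j in range(6)], y).r2 <= 0.02

    def test_more_genes_than_strains_error(self, rng):
        vals = rng.integers(0, 2, (8, 10))
        genes = _genes(vals, [f"G{j}" for j in range(10)])
        y = pd.Series(rng.normal(size=8), index=genes.values.index)
        with pytest.raises(ValueError, match="more genes"):
            og.variance_explained(genes, [f"G{j}" for j in range(10)], y)
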