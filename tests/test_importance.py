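"""Permutation-null importance, consensus selection, FDR, enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import ontogwas as og
from ontogwas.importance import (FoldImportance, compare_top_features,
                                 consensus_features, enrich_features,
                                 permutation_importance, scramble_matrix)
from ontogwas.ontology import Ontology

FAST = og.ModelConfig(n_trees=40, engine="lightgbm")


class TestEmpiricalP:
    def test_plus_one_floor_and_ceiling(self):
        obs = pd.Series({"a": 10.0, "b": 0.0})
        null = pd.DataFrame({"a": np.linspace(0, 5, 100),
                             "b": np.linspace(1, 5, 100)})
        fi = FoldImportance(obs, null)
        assert fi.pvalues["a"] == pytest.approx(1 / 101)
        assert fi.pvalues["b"] == pytest.approx(1.0)

    def test_invariant_under_monotone_rescaling(self, rng):
        obs = pd.Series(rng.normal(size=8) ** 2, index=list("abcdefgh"))
        null = pd.DataFrame(rng.normal(size=(50, 8)) ** 2, columns=obs.index)
        p1 = FoldImportance(obs, null).pvalues
        p2 = FoldImportance(np.sqrt(obs), np.sqrt(null)).pvalues
        assert (p1 == p2).all()

    def test_perfect_feature_hits_floor_in_real_fit(self, rng):
        X = pd.DataFrame(rng.normal(size=(120, 8)))
        y = X[0].to_numpy().copy()
        fi = permutation_importance(X, y, backend="rf", n_perm=20, seed=1,
                                    config=FAST)
        assert fi.pvalues[0] == pytest.approx(1 / 21)

    def test_requires_importance_measure(self, rng):
        with pytest.raises(ValueError, match="importance"):
            permutation_importance(pd.DataFrame(rng.normal(size=(30, 3))),
                                   rng.normal(size=30), backend="ridge",
                                   n_perm=2)


class TestConsensus:
    def _fi(self, pvals, imps=None):
        n = len(pvals)
        obs = pd.Series(imps if imps is not None else np.ones(n),
                        index=[f"f{i}" for i in range(n)])
        # craft a null that reproduces the requested p values exactly
        null = pd.DataFrame(
            {f"f{i}": np.where(np.arange(100) < round(p * 101) - 1, 2.0, 0.0)
             for i, p in enumerate(pvals)})
        fi = FoldImportance(obs, null)
        return fi

    def test_all_folds_rule(self):
        folds = [self._fi([0.005, 0.005]) for _ in range(4)]
        folds.append(self._fi([0.005, 0.02]))
        got = consensus_features(folds, alpha=0.01)
        assert got == ["f0"]

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_bruteforce_filter(self, seed):
        rng = np.random.default_rng(seed)
        pvals = pd.DataFrame(rng.uniform(size=(20, 5)) * 0.05,
                             index=[f"f{i}" for i in range(20)])
        got = consensus_features(pvals, alpha=0.01)
        expect = {f for f in pvals.index if (pvals.loc[f] < 0.01).all()}
        assert set(got) == expect

    def test_shrinks_as_alpha_decreases(self, rng):
        pvals = pd.DataFrame(rng.uniform(size=(30, 5)) * 0.1,
                             index=[f"f{i}" for i in range(30)])
        sets = [set(consensus_features(pvals, alpha=a))
                for a in (0.1, 0.05, 0.01, 0.001)]
        for bigger, smaller in zip(sets, sets[1:]):
            assert smaller <= bigger

    def test_mismatched_universes_error(self):
        a = self._fi([0.005])
        b = self._fi([0.005, 0.005])
        with pytest.raises(ValueError, match="universes differ"):
            consensus_features([a, b])

    def test_ordering_by_mean_importance(self):
        folds = [self._fi([0.005, 0.005, 0.005], imps=[1.0, 3.0, 2.0])
                 for _ in range(3)]
        assert consensus_features(folds, alpha=0.01) == ["f1", "f2", "f0"]


class TestScrambleAndFdr:
    def test_scramble_preserves_marginals(self, rng):
        X = pd.DataFrame(rng.poisson(2, (50, 6)).astype(float))
        S = scramble_matrix(X, seed=3)
        assert S.shape == X.shape
        for col in X.columns:
            assert sorted(S[col]) == sorted(X[col])
        assert not S.equals(X)
        assert scramble_matrix(X, seed=3).equals(S)

    def test_null_data_yields_zero_over_zero(self, rng):
        # nothing is selected on either the real or the scrambled matrix
        X = pd.DataFrame(rng.normal(size=(60, 8)))
        y = pd.Series(rng.normal(size=60), index=X.index)
        fdr, obs, null = og.empirical_fdr(X, y, backend="rf", config=FAST,
                                          n_folds=3, n_perm=20, alpha=0.01,
                                          seed=5)
        assert obs.consensus_selected == [] and null.consensus_selected == []
        assert fdr == 0.0

    def test_planted_signal_low_fdr(self, rng):
        X = pd.DataFrame(rng.poisson(1.5, (150, 10)).astype(float))
        y = pd.Series(-1.0 * X[2].to_numpy() + 0.3 * rng.normal(size=150),
                      index=X.index)
        fdr, obs, _ = og.empirical_fdr(X, y, backend="rf", config=FAST,
                                       n_folds=5, n_perm=100, alpha=0.01,
                                       seed=6)
        assert 2 in obs.consensus_selected
        assert fdr <= 0.2


def _hypergeom_tail_oracle(M, K, N, x):
    """P(X >= x) by full enumeration of the sampling space."""
    total = math.comb(M, N)
    return sum(math.comb(K, k) * math.comb(M - K, N - k)
               for k in range(x, min(K, N) + 1)) / total


class TestEnrichment:
    def _ont(self, term_genes):
        return Ontology([(t, "root") for t in term_genes], term_genes)

    def test_exact_small_universe(self):
        universe = [f"g{i}" for i in range(10)]
        ont = self._ont({"T": set(universe[:5])})
        df = enrich_features(universe[:5], ont, universe)
        assert df.loc["T", "p_raw"] == pytest.approx(1 / 252)

    def test_term_covering_universe_is_uninformative(self):
        universe = [f"g{i}" for i in range(8)]
        ont = self._ont({"T": set(universe)})
        df = enrich_features(universe[:3], ont, universe)
        assert df.loc["T", "p_raw"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        M = int(rng.integers(6, 15))
        universe = [f"g{i}" for i in range(M)]
        K = int(rng.integers(1, M))
        term_genes = set(rng.choice(universe, size=K, replace=False))
        N = int(rng.integers(1, M))
        selection = list(rng.choice(universe, size=N, replace=False))
        ont = self._ont({"T": term_genes})
        df = enrich_features(selection, ont, universe)
        x = len(term_genes & set(selection))
        assert df.loc["T", "p_raw"] == pytest.approx(
            _hypergeom_tail_oracle(M, K, N, x))

    def test_empty_selection_error(self):
        ont = self._ont({"T": {"g0"}})
        with pytest.raises(ValueError, match="empty gene set"):
            enrich_features([], ont, ["g0"])


class TestCompareTopFeatures:
    def test_identical_lists_strong_overlap(self):
        top = [f"f{i}" for i in range(5)]
        odds, p = compare_top_features(top, top, universe_size=50)
        assert odds > 100
        # oracle: exact two-sided tail over all fixed-margin tables
        oracle = _fisher_two_sided(5, 0, 0, 50)
        assert p == pytest.approx(oracle, rel=1e-9)
        assert p < 1e-6

    def test_disjoint_three_of_six(self):
        odds, p = compare_top_features(["a", "b", "c"], ["d", "e", "f"],
                                       universe_size=6)
        assert p == pytest.approx(0.1)
        assert odds < 1

    def test_independent_draws_median_odds_near_one(self):
        rng = np.random.default_rng(9)
        universe = [f"f{i}" for i in range(60)]
        odds = []
        for _ in range(100):
            a = list(rng.choice(universe, 10, replace=False))
            b = list(rng.choice(universe, 10, replace=False))
            odds.append(compare_top_features(a, b, 60)[0])
        med = np.median(odds)
        assert 1 / 3 <= med <= 3

    def test_k_exceeding_universe_error(self):
        with pytest.raises(ValueError, match="universe"):
            compare_top_features(list("abc"), list("def"), universe_size=2)


def _fisher_two_sided(both, na, nb, universe):
    """Point-probability-rule two-sided Fisher P by enumeration."""
    from scipy.stats import hypergeom

    k_a = both + na
    k_b = both + nb
    probs = [hypergeom.pmf(x, universe, k_a, k_b)
             for x in range(max(0, k_a + k_b - universe), min(k_a, k_b) + 1)]
    p_obs = hypergeom.pmf(both, universe, k_a, k_b)
    return sum(p for p in probs if p <= p_obs * (1 + 1e-9))
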