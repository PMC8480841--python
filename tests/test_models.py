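"""Cross-validated predictors: folds, determinism, backend behaviour."""

import warnings

import numpy as np
import pandas as pd
import pytest

import ontogwas as og
from ontogwas.backends import ModelConfig
from ontogwas.models import make_folds


def _df(arr, prefix="f"):
    return pd.DataFrame(arr, index=[f"s{i}" for i in range(len(arr))],
                        columns=[f"{prefix}{j}" for j in range(arr.shape[1])])


class TestFolds:
    @pytest.mark.parametrize("n", [50, 53, 104])
    def test_partition_into_near_equal_folds(self, n):
        a = make_folds(n, 5, seed=3)
        sizes = np.bincount(a, minlength=5)
        assert sizes.sum() == n
        assert sizes.max() - sizes.min() <= 1
        # remainders land on the earliest folds
        assert sorted(sizes, reverse=True) == list(sizes)

    def test_deterministic(self):
        assert np.array_equal(make_folds(40, 5, 9), make_folds(40, 5, 9))
        assert not np.array_equal(make_folds(40, 5, 9), make_folds(40, 5, 10))


class TestCrossValidate:
    def test_perfect_linear_signal_ridge(self, rng):
        y = pd.Series(rng.normal(size=100), index=[f"s{i}" for i in range(100)])
        X = _df(np.column_stack([y.to_numpy(), rng.normal(size=(100, 3))]))
        res = og.cross_validate(X, y, backend="ridge", seed=0)
        assert res.mean_r2 > 0.99

    def test_null_phenotype_low_r2_in_expectation(self):
        scores = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = _df(rng.normal(size=(100, 20)))
            y = pd.Series(rng.normal(size=100), index=X.index)
            scores.append(og.cross_validate(X, y, backend="ridge",
                                            seed=seed).mean_r2)
        assert np.mean(scores) <= 0.05

    @pytest.mark.parametrize("engine", ["sklearn", "lightgbm"])
    def test_same_seed_same_result(self, rng, engine):
        X = _df(rng.normal(size=(60, 10)))
        y = pd.Series(X.iloc[:, 0] + 0.5 * rng.normal(size=60), index=X.index)
        cfg = ModelConfig(n_trees=30, engine=engine)
        a = og.cross_validate(X, y, backend="rf", config=cfg, seed=4)
        b = og.cross_validate(X, y, backend="rf", config=cfg, seed=4)
        assert np.array_equal(a.per_fold_r2, b.per_fold_r2)
        assert (a.fold_assignment == b.fold_assignment).all()

    def test_unknown_backend_and_constant_phenotype(self, rng):
        X = _df(rng.normal(size=(30, 4)))
        y = pd.Series(np.ones(30), index=X.index)
        with pytest.raises(ValueError, match="constant phenotype"):
            og.TraitModel(X, y, backend="rf")
        y2 = pd.Series(rng.normal(size=30), index=X.index)
        with pytest.raises(ValueError, match="unknown backend"):
            og.TraitModel(X, y2, backend="boost")

    def test_summary_mentions_backend_and_mean(self, rng, small_study):
        res = og.cross_validate(small_study.ontotypes, small_study.phenotypes,
                                "growth", backend="ridge", seed=1)
        text = res.summary()
        assert "ridge" in text and "mean R2" in text


class TestRandomForest:
    def test_planted_feature_has_top_importance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 20))
        y = X[:, 1].copy()
        model = og.fit_random_forest(X, y, og.ModelConfig(n_trees=100), seed=2)
        imp = model.importances()
        assert np.argmax(imp) == 1

    def test_constant_y_predicts_constant(self, rng):
        X = rng.normal(size=(30, 5))
        model = og.fit_random_forest(X, np.full(30, 7.0),
                                     og.ModelConfig(n_trees=10), seed=0)
        assert np.allclose(model.predict(X), 7.0)

    def test_training_fit_on_noiseless_signal(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(300, 5))
        y = X[:, 0] + 2 * X[:, 1]
        cfg = og.ModelConfig(n_trees=200, min_samples_leaf=1, max_features=1.0)
        model = og.fit_random_forest(X, y, cfg, seed=1)
        r2 = 1 - np.sum((model.predict(X) - y) ** 2) / np.sum((y - y.mean()) ** 2)
        assert r2 >= 0.9

    def test_n_trees_validation(self):
        with pytest.raises(ValueError, match="n_trees"):
            og.make_backend("rf", og.ModelConfig(n_trees=0))


class TestBlup:
    def test_huge_delta_shrinks_to_mean(self, rng):
        Z = rng.integers(0, 2, (30, 50)).astype(float)
        y = rng.normal(size=30)
        model = og.fit_blup(Z, y, delta=1e8)
        assert np.allclose(model.predict_train(), y.mean(), atol=1e-5)

    def test_zero_delta_interpolates(self, rng):
        Z = rng.normal(size=(30, 50))
        y = rng.normal(size=30)
        model = og.fit_blup(Z, y, delta=0.0)
        assert np.allclose(model.predict_train(), y, atol=1e-6)

    @pytest.mark.parametrize("seed", range(3))
    def test_equals_ridge_on_standardized_genotypes(self, seed):
        from sklearn.linear_model import Ridge

        from ontogwas.lmm import standardize_genotypes

        rng = np.random.default_rng(seed)
        Z = rng.integers(0, 2, (30, 50)).astype(float)
        y = rng.normal(size=30)
        delta = 0.5 + seed
        model = og.fit_blup(Z, y, delta=delta)
        Zs, *_ = standardize_genotypes(Z)
        ridge = Ridge(alpha=Zs.shape[1] * delta, fit_intercept=True).fit(Zs, y)
        assert np.abs(model.predict(Z) - ridge.predict(Zs)).max() < 1e-6


class TestMixedRandomForest:
    def test_identity_kinship_matches_plain_rf(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(120, 10))
        y = np.sin(X[:, 0]) + X[:, 1] + 0.3 * rng.normal(size=120)
        cfg = og.ModelConfig(n_trees=60)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mixed = og.fit_mixed_random_forest(X, y, np.eye(120), cfg, seed=3)
        plain = og.fit_random_forest(X, y, cfg, seed=3)
        r = np.corrcoef(mixed.predict(X), plain.predict(X))[0, 1]
        assert r >= 0.9

    def test_recovers_structured_variance(self):
        rng = np.random.default_rng(8)
        n, blocks = 150, 5
        labels = np.arange(n) % blocks
        K = (labels[:, None] == labels[None, :]).astype(float)
        y = np.array([rng.normal()] * 1)  # placeholder
        offsets = rng.normal(size=blocks) * 2.0
        y = offsets[labels] + 0.5 * rng.normal(size=n)
        X = rng.normal(size=(n, 10))  # pure noise features
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = og.fit_mixed_random_forest(X, y, K,
                                               og.ModelConfig(n_trees=60), seed=4)
        ratio = model.sigma2_g / (model.sigma2_g + model.sigma2_e)
        assert ratio >= 0.5

    def test_constant_y_degenerate(self, rng):
        X = rng.normal(size=(30, 4))
        model = og.fit_mixed_random_forest(X, np.ones(30), np.eye(30),
                                           og.ModelConfig(n_trees=10), seed=0)
        assert model.sigma2_g == 0.0 and model.sigma2_e == 0.0
        assert np.allclose(model.predict(X), 1.0)

    def test_requires_kinship(self, rng):
        X = _df(rng.normal(size=(40, 5)))
        y = pd.Series(rng.normal(size=40), index=X.index)
        with pytest.raises(ValueError, match="kinship"):
            og.TraitModel(X, y, backend="mixed_rf")

    def test_not_catastrophically_worse_on_unstructured_data(self):
        # held-out R2 difference (mixed - plain) averaged over null seeds
        diffs = []
        cfg = og.ModelConfig(n_trees=30)
        for seed in range(10):
            rng = np.random.default_rng(300 + seed)
            X = _df(rng.normal(size=(80, 10)))
            y = pd.Series(rng.normal(size=80), index=X.index)
            K = pd.DataFrame(np.eye(80), index=X.index, columns=X.index)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rm = og.cross_validate(X, y, backend="mixed_rf", kinship=K,
                                       config=cfg, seed=seed)
                rr = og.cross_validate(X, y, backend="rf", config=cfg, seed=seed)
            diffs.append(rm.mean_r2 - rr.mean_r2)
        assert np.mean(diffs) >= -0.1
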