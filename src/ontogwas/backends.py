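"""Prediction backends: forests, mixed forests and linear genomic predictors.

All backends share a small estimator surface: ``fit(X, y, seed, K_tt=None)``
and ``predict(X, K_xt=None)``, where the kinship blocks are only consumed by
the structure-aware backends (mixed random forest, GBLUP).  Forest
hyperparameter defaults follow the ranger regression defaults (mtry =
sqrt(p), minimum node size 5) with 1000 bootstrap-sampled trees.

Two forest engines are available: scikit-learn (reference engine; supports
out-of-bag prediction and OOB permutation importance) and LightGBM in random
forest mode (several-fold faster tree growth; used by the permutation-null
pipelines, which fit hundreds of forests).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg

from . import lmm
from ._utils import substream_seed

__all__ = [
    "ModelConfig",
    "RandomForestBackend",
    "MixedRandomForestBackend",
    "BLUPBackend",
    "RidgeBackend",
    "LassoBackend",
    "MLPBackend",
    "make_backend",
    "BACKENDS",
]


@dataclass
class ModelConfig:
    """Tunable knobs shared by all backends."""

    n_trees: int = 1000
    engine: str = "sklearn"  # or "lightgbm"
    max_features: str | float = "sqrt"
    min_samples_leaf: int = 5
    max_depth: int | None = None
    importance_measure: str = "impurity"  # or "oob_permutation"
    # mixed random forest
    mixed_tol: float = 1e-4
    mixed_max_iter: int = 20
    # GBLUP
    blup_delta: float | None = None  # sigma2_e / sigma2_g; REML-estimated if None
    # penalised linear models
    penalty_grid: tuple = tuple(np.logspace(-6, 6, 25))
    inner_cv: int = 3
    # neural net
    mlp_hidden: tuple = (1000, 400, 100)
    mlp_max_iter: int = 300


class RandomForestBackend:
    """Bootstrap-aggregated regression trees."""

    name = "rf"
    needs_kinship = False

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        if self.config.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        self._model = None
        self._X = None
        self._y = None

    def fit(self, X, y, seed: int = 0, K_tt=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        cfg = self.config
        if cfg.engine == "sklearn":
            from sklearn.ensemble import RandomForestRegressor

            self._model = RandomForestRegressor(
                n_estimators=cfg.n_trees,
                max_features=cfg.max_features,
                min_samples_leaf=cfg.min_samples_leaf,
                max_depth=cfg.max_depth,
                bootstrap=True,
                oob_score=False,
                random_state=int(seed) & 0x7FFFFFFF,
                n_jobs=1,
            ).fit(X, y)
        elif cfg.engine == "lightgbm":
            import lightgbm as lgb

            p = X.shape[1]
            colsample = max(np.sqrt(p) / p, 1.0 / p) if p > 1 else 1.0
            self._model = lgb.LGBMRegressor(
                boosting_type="rf",
                n_estimators=cfg.n_trees,
                subsample=0.632,
                subsample_freq=1,
                colsample_bytree=colsample,
                min_child_samples=cfg.min_samples_leaf,
                max_depth=cfg.max_depth if cfg.max_depth is not None else -1,
                num_leaves=64,
                random_state=int(seed) & 0x7FFFFFFF,
                n_jobs=1,
                verbose=-1,
                importance_type="gain",
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                self._model.fit(X, y)
        else:
            raise ValueError(f"unknown forest engine {cfg.engine!r}")
        self._X, self._y = X, y
        return self

    def predict(self, X, K_xt=None) -> np.ndarray:
        with warnings.catch_warnings():
            # lightgbm's sklearn wrapper records synthetic feature names even
            # for array input and then complains about their absence
            warnings.simplefilter("ignore", UserWarning)
            return np.asarray(self._model.predict(np.asarray(X, dtype=float)))

    def oob_prediction(self) -> np.ndarray:
        """Per-sample prediction from trees that did not see the sample."""
        cfg = self.config
        if cfg.engine != "sklearn":
            raise ValueError("out-of-bag predictions require the sklearn engine")
        from sklearn.ensemble import _forest as _f

        n = len(self._y)
        total = np.zeros(n)
        counts = np.zeros(n)
        n_boot = _f._get_n_samples_bootstrap(n, self._model.max_samples, None)
        for tree in self._model.estimators_:
            oob = _f._generate_unsampled_indices(tree.random_state, n, n_boot, None)
            total[oob] += tree.predict(self._X[oob])
            counts[oob] += 1
        pred = np.where(counts > 0, total / np.maximum(counts, 1), self._y.mean())
        return pred

    def importances(self, measure: str | None = None, seed: int = 0) -> np.ndarray:
        measure = measure or self.config.importance_measure
        if measure in ("impurity", "gain"):
            return np.asarray(self._model.feature_importances_, dtype=float)
        if measure == "oob_permutation":
            return self._oob_permutation_importance(seed)
        raise ValueError(f"unknown importance measure {measure!r}")

    def _oob_permutation_importance(self, seed: int) -> np.ndarray:
        """Mean decrease in OOB MSE when each feature is permuted."""
        if self.config.engine != "sklearn":
            raise ValueError("OOB permutation importance requires the sklearn engine")
        from sklearn.ensemble import _forest as _f

        X, y = self._X, self._y
        n, p = X.shape
        rng = np.random.default_rng(seed)
        imp = np.zeros(p)
        n_boot = _f._get_n_samples_bootstrap(n, self._model.max_samples, None)
        for tree in self._model.estimators_:
            oob = _f._generate_unsampled_indices(tree.random_state, n, n_boot, None)
            if len(oob) < 2:
                continue
            Xo = X[oob]
            base = np.mean((tree.predict(Xo) - y[oob]) ** 2)
            for j in range(p):
                Xp = Xo.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                imp[j] += np.mean((tree.predict(Xp) - y[oob]) ** 2) - base
        return imp / len(self._model.estimators_)


class MixedRandomForestBackend(RandomForestBackend):
    """Forest plus a kinship-distributed random effect.

    Fits ``y = f(X) + g + e`` with ``g ~ N(0, sigma2_g K)`` by alternating
    (i) a forest fit on ``y - g_hat`` and (ii) REML variance components and
    BLUP of ``g`` on the out-of-bag forest residuals.  Out-of-bag residuals
    (rather than in-sample fitted values) are used in step (ii) so that the
    forest's overfit does not swallow the structured variance.
    """

    name = "mixed_rf"
    needs_kinship = True

    def __init__(self, config: ModelConfig | None = None):
        super().__init__(config)
        if self.config.engine != "sklearn":
            # OOB residuals drive the variance step
            self.config = replace(self.config, engine="sklearn")
        self.sigma2_g = 0.0
        self.sigma2_e = 0.0
        self.g_hat = None
        self.n_iter_ = 0
        self.converged_ = False

    def fit(self, X, y, seed: int = 0, K_tt=None):
        if K_tt is None:
            raise ValueError("mixed random forest requires a kinship matrix")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        K_tt = np.asarray(K_tt, dtype=float)
        w = linalg.eigvalsh(K_tt)
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise ValueError(f"kinship not PSD (min eigenvalue {w.min():.3g})")
        self._K_tt = K_tt
        n = len(y)
        if np.var(y) == 0:
            # degenerate: constant response
            super().fit(X, y, seed=seed)
            self.sigma2_g = self.sigma2_e = 0.0
            self.g_hat = np.zeros(n)
            self._r_oob = np.zeros(n)
            self.converged_ = True
            return self

        g_hat = np.zeros(n)
        prev_sg = None
        # one fixed forest seed across iterations: the bootstrap draws stay
        # put, so the alternation is a deterministic fixed-point iteration
        fit_seed = substream_seed(seed, "mixed")
        for it in range(self.config.mixed_max_iter):
            super().fit(X, y - g_hat, seed=fit_seed)
            r = y - self.oob_prediction()
            sg, se = lmm.reml_single(r, K_tt, check=False)
            g_hat = lmm.blup_solve(K_tt, r, sg, se)
            self.n_iter_ = it + 1
            if prev_sg is not None:
                denom = max(abs(prev_sg), 1e-12)
                if abs(sg - prev_sg) / denom < self.config.mixed_tol:
                    self.converged_ = True
                    prev_sg = sg
                    break
            prev_sg = sg
        else:
            warnings.warn(
                f"mixed random forest did not converge in "
                f"{self.config.mixed_max_iter} iterations; using last iterate"
            )
        self.sigma2_g, self.sigma2_e = prev_sg, se
        self.g_hat = g_hat
        # final forest on the structure-adjusted response
        super().fit(X, y - g_hat, seed=fit_seed)
        self._r_oob = y - (self.oob_prediction() + g_hat)
        self._r_for_blup = y - self.oob_prediction()
        return self

    def predict(self, X, K_xt=None) -> np.ndarray:
        f = super().predict(X)
        if K_xt is None or self.sigma2_g <= 0:
            return f
        g = lmm.blup_solve(
            self._K_tt, self._r_for_blup, self.sigma2_g, self.sigma2_e,
            K_xt=np.asarray(K_xt, dtype=float),
        )
        return f + g


class BLUPBackend:
    """GBLUP: best linear unbiased prediction from a genomic relationship matrix.

    The feature matrix is standardised column-wise into Z, the kinship is
    ``K = Z Z' / m`` and the genetic values are
    ``g_hat = K (K + delta I)^-1 (y - ybar)`` with ``delta = sigma2_e /
    sigma2_g`` estimated by REML unless supplied.  Held-out strains are
    predicted through the cross-kinship ``Z* Z' / m``.
    """

    name = "blup"
    needs_kinship = False

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()

    def fit(self, X, y, seed: int = 0, K_tt=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        Z, mean, std, kept = lmm.standardize_genotypes(X)
        self._mean, self._std, self._kept = mean, std, kept
        self._Z = Z
        m = Z.shape[1]
        K = (Z @ Z.T) / m
        self._K = K
        self.ybar_ = float(y.mean())
        r = y - self.ybar_
        delta = self.config.blup_delta
        if delta is None:
            sg, se = lmm.reml_single(y, K, check=False)
            delta = np.inf if sg <= 0 else se / sg
        self.delta_ = float(delta)
        n = len(y)
        if np.isinf(self.delta_):
            self._alpha = np.zeros(n)
        elif self.delta_ == 0.0:
            # column standardisation puts the ones vector in K's null space,
            # but the centred residual lies in K's range, so a least-squares
            # solve interpolates exactly when K has full rank otherwise
            alpha, _, rank, _ = np.linalg.lstsq(K, r, rcond=None)
            if rank < n - 1:
                raise linalg.LinAlgError(
                    "(K + delta*I) is singular with delta=0; "
                    "supply a positive blup_delta")
            self._alpha = alpha
        else:
            A = K + self.delta_ * np.eye(n)
            self._alpha = linalg.solve(A, r, assume_a="pos")
        return self

    def _cross_kinship(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Zx = (X[:, self._kept] - self._mean[self._kept]) / self._std[self._kept]
        return (Zx @ self._Z.T) / self._Z.shape[1]

    def predict(self, X, K_xt=None) -> np.ndarray:
        return self.ybar_ + self._cross_kinship(X) @ self._alpha

    def predict_train(self) -> np.ndarray:
        return self.ybar_ + self._K @ self._alpha


class _SklearnLinear:
    needs_kinship = False

    def fit(self, X, y, seed: int = 0, K_tt=None):
        from sklearn.model_selection import KFold

        cv = KFold(
            n_splits=self.config.inner_cv, shuffle=True,
            random_state=int(seed) & 0x7FFFFFFF,
        )
        self._model = self._build(cv, seed).fit(
            np.asarray(X, dtype=float), np.asarray(y, dtype=float).ravel()
        )
        return self

    def predict(self, X, K_xt=None) -> np.ndarray:
        return np.asarray(self._model.predict(np.asarray(X, dtype=float)))


class RidgeBackend(_SklearnLinear):
    """Ridge regression; penalty picked by inner cross-validation."""

    name = "ridge"

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()

    def _build(self, cv, seed):
        from sklearn.linear_model import RidgeCV

        return RidgeCV(alphas=list(self.config.penalty_grid), cv=cv)


class LassoBackend(_SklearnLinear):
    """Lasso regression; penalty picked by inner cross-validation."""

    name = "lasso"

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()

    def _build(self, cv, seed):
        from sklearn.linear_model import LassoCV

        return LassoCV(
            alphas=list(self.config.penalty_grid), cv=cv,
            random_state=int(seed) & 0x7FFFFFFF, max_iter=5000,
        )


class MLPBackend:
    """Fully connected network: 3 sigmoid hidden layers (1000, 400, 100)."""

    name = "mlp"
    needs_kinship = False

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()

    def fit(self, X, y, seed: int = 0, K_tt=None):
        from sklearn.neural_network import MLPRegressor

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._model = MLPRegressor(
                hidden_layer_sizes=tuple(self.config.mlp_hidden),
                activation="logistic",
                max_iter=self.config.mlp_max_iter,
                random_state=int(seed) & 0x7FFFFFFF,
            ).fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float).ravel())
        return self

    def predict(self, X, K_xt=None) -> np.ndarray:
        return np.asarray(self._model.predict(np.asarray(X, dtype=float)))


BACKENDS = {
    "rf": RandomForestBackend,
    "mixed_rf": MixedRandomForestBackend,
    "blup": BLUPBackend,
    "ridge": RidgeBackend,
    "lasso": LassoBackend,
    "mlp": MLPBackend,
}


def make_backend(name: str, config: ModelConfig | None = None):
    try:
        cls = BACKENDS[name]
    except KeyError:
        raise ValueError(f"unknown backend {name!r}; choose from {sorted(BACKENDS)}")
    return cls(config)
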