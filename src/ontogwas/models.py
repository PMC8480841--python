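"""Phenotype prediction models with cross-validated evaluation.

The central object is :class:`TraitModel`: it is built from a feature matrix
(ontotype, gene or SNV level), one trait of a phenotype table, and optionally
a kinship matrix, and its :meth:`TraitModel.fit` returns a :class:`CVResults`
object carrying per-fold held-out R^2 values, the fold assignment, the fitted
fold predictors and (for structure-aware backends) variance components.
Importance analysis hangs off the results object.

Evaluation is 5-fold cross-validation: strains are randomly partitioned into
five near-equal subsamples, each held out once, and the model's score is the
average held-out R^2 (coefficient of determination).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import as_frame, substream_seed
from .backends import BACKENDS, ModelConfig, make_backend

__all__ = [
    "TraitModel",
    "CVResults",
    "cross_validate",
    "make_folds",
    "read_phenotypes",
    "fit_random_forest",
    "fit_mixed_random_forest",
    "fit_blup",
]


def read_phenotypes(path) -> pd.DataFrame:
    """Strain x trait table (TSV, first column = strain ID); blanks allowed."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def make_folds(n: int, n_folds: int, seed: int) -> np.ndarray:
    """Seeded shuffle then contiguous split; remainders go to earliest folds.

    Returns an array mapping each of the *n* positions to a fold id.
    """
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if n < n_folds:
        raise ValueError(f"cannot split {n} strains into {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    base, rem = divmod(n, n_folds)
    sizes = [base + (1 if k < rem else 0) for k in range(n_folds)]
    assignment = np.empty(n, dtype=int)
    start = 0
    for k, size in enumerate(sizes):
        assignment[order[start:start + size]] = k
        start += size
    return assignment


def _r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        return np.nan
    return 1.0 - ss_res / ss_tot


@dataclass
class CVResults:
    """Cross-validated fit of one backend on one trait."""

    backend: str
    per_fold_r2: np.ndarray
    fold_assignment: pd.Series  # strain -> fold
    seed: int
    trait: str | None = None
    models: list = field(default_factory=list, repr=False)
    variance_components: list[dict] = field(default_factory=list)
    config: ModelConfig | None = field(default=None, repr=False)
    _model: "TraitModel | None" = field(default=None, repr=False)

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.per_fold_r2))

    @property
    def n_folds(self) -> int:
        return len(self.per_fold_r2)

    def summary(self) -> str:
        lines = [
            "Cross-validated phenotype prediction",
            "=" * 44,
            f"backend:        {self.backend}",
            f"trait:          {self.trait or '-'}",
            f"strains:        {len(self.fold_assignment)}",
            f"folds:          {self.n_folds}   (seed {self.seed})",
            "-" * 44,
        ]
        for k, r2 in enumerate(self.per_fold_r2):
            extra = ""
            if self.variance_components:
                vc = self.variance_components[k]
                if vc:
                    extra = (f"   sigma2_g={vc['sigma2_g']:.4g}"
                             f" sigma2_e={vc['sigma2_e']:.4g}")
                lines.append(f"fold {k}:  R2 = {r2:+.4f}{extra}")
            else:
                lines.append(f"fold {k}:  R2 = {r2:+.4f}")
        lines += ["-" * 44, f"mean R2:        {self.mean_r2:+.4f}"]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "backend": self.backend,
            "trait": self.trait,
            "per_fold_r2": [float(v) for v in self.per_fold_r2],
            "mean_r2": self.mean_r2,
            "seed": int(self.seed),
            "n_strains": int(len(self.fold_assignment)),
            "variance_components": self.variance_components,
        }

    # -- downstream analyses ------------------------------------------------

    def permutation_importance(self, n_perm: int = 100, alpha: float = 0.01,
                               seed: int | None = None):
        """Per-fold response-permutation importance and consensus selection."""
        from .importance import run_importance_analysis

        m = self._require_model()
        return run_importance_analysis(
            m.features, m.phenotype, backend=self.backend, config=self.config,
            n_folds=self.n_folds, n_perm=n_perm, alpha=alpha,
            seed=self.seed if seed is None else seed, kinship=m.kinship,
        )

    def _require_model(self) -> "TraitModel":
        if self._model is None:
            raise ValueError("results were not produced by a TraitModel")
        return self._model


class TraitModel:
    """Phenotype predictor for one trait over a feature matrix.

    Parameters
    ----------
    features
        Strains x features DataFrame (or an object with a ``values``
        DataFrame such as :class:`~ontogwas.ontotype.OntotypeMatrix`).
    phenotype
        Series of trait values indexed by strain (missing cells allowed and
        dropped).
    backend
        One of ``rf``, ``mixed_rf``, ``blup``, ``ridge``, ``lasso``, ``mlp``.
    kinship
        Strains x strains relatedness (DataFrame or
        :class:`~ontogwas.genetics.Kinship`); required by ``mixed_rf``.
    """

    def __init__(self, features, phenotype: pd.Series, backend: str = "mixed_rf",
                 kinship=None, config: ModelConfig | None = None):
        features = as_frame(features)
        if backend not in BACKENDS:
            raise ValueError(
                f"unknown backend {backend!r}; choose from {sorted(BACKENDS)}")
        phenotype = pd.Series(phenotype).dropna().astype(float)
        shared = features.index.intersection(phenotype.index)
        if len(shared) < 10:
            raise ValueError(
                f"only {len(shared)} strains shared between features and "
                "phenotype (need >= 10)")
        self.features = features.loc[shared]
        self.phenotype = phenotype.loc[shared]
        if self.phenotype.nunique() <= 1:
            raise ValueError("constant phenotype: R2 is undefined")
        self.backend = backend
        self.config = config or ModelConfig()
        kin = as_frame(kinship)
        if kin is not None:
            kin = kin.loc[shared, shared]
        self.kinship = kin
        if BACKENDS[backend].needs_kinship and kin is None:
            raise ValueError(f"backend {backend!r} requires a kinship matrix")

    @classmethod
    def from_matrices(cls, feature_matrix, phenotypes: pd.DataFrame, trait: str,
                      **kwargs) -> "TraitModel":
        if trait not in phenotypes.columns:
            raise KeyError(f"trait {trait!r} not in phenotype table")
        m = cls(feature_matrix, phenotypes[trait], **kwargs)
        m._trait = trait
        return m

    def fit(self, n_folds: int = 5, seed: int = 0) -> CVResults:
        y = self.phenotype.to_numpy()
        X = self.features.to_numpy(dtype=float)
        n = len(y)
        if n < 2 * n_folds:
            raise ValueError(f"{n} strains is too few for {n_folds}-fold CV")
        assignment = make_folds(n, n_folds, substream_seed(seed, "folds"))
        per_fold = np.empty(n_folds)
        models = []
        var_comps = []
        for k in range(n_folds):
            tr = assignment != k
            te = ~tr
            backend = make_backend(self.backend, self.config)
            K_tt = K_xt = None
            if self.kinship is not None:
                K = np.asarray(self.kinship, dtype=float)
                K_tt = K[np.ix_(tr, tr)]
                K_xt = K[np.ix_(te, tr)]
            backend.fit(X[tr], y[tr], seed=substream_seed(seed, "fit", k),
                        K_tt=K_tt)
            pred = backend.predict(X[te], K_xt=K_xt)
            per_fold[k] = _r2(y[te], pred)
            models.append(backend)
            vc = {}
            if hasattr(backend, "sigma2_g"):
                vc = {"sigma2_g": float(backend.sigma2_g),
                      "sigma2_e": float(backend.sigma2_e)}
            var_comps.append(vc)
        return CVResults(
            backend=self.backend,
            per_fold_r2=per_fold,
            fold_assignment=pd.Series(assignment, index=self.features.index,
                                      name="fold"),
            seed=seed,
            trait=getattr(self, "_trait", getattr(self.phenotype, "name", None)),
            models=models,
            variance_components=var_comps,
            config=self.config,
            _model=self,
        )


def cross_validate(features, pheno, trait: str | None = None,
                   backend: str = "rf", config: ModelConfig | None = None,
                   seed: int = 0, n_folds: int = 5, kinship=None) -> CVResults:
    """Functional wrapper around :class:`TraitModel`.

    ``pheno`` may be a Series (one trait) or a strain x trait DataFrame with
    ``trait`` naming the column.
    """
    if isinstance(pheno, pd.DataFrame):
        if trait is None:
            raise ValueError("trait name required with a phenotype table")
        model = TraitModel.from_matrices(features, pheno, trait, backend=backend,
                                         kinship=kinship, config=config)
    else:
        model = TraitModel(features, pheno, backend=backend, kinship=kinship,
                           config=config)
    return model.fit(n_folds=n_folds, seed=seed)


# -- thin fitted-predictor constructors -------------------------------------


def fit_random_forest(X, y, config: ModelConfig | None = None, seed: int = 0):
    """Fit a bootstrap regression forest; returns the fitted backend."""
    return make_backend("rf", config).fit(np.asarray(X, float),
                                          np.asarray(y, float), seed=seed)


def fit_mixed_random_forest(X, y, K, config: ModelConfig | None = None,
                            seed: int = 0):
    """Fit forest + kinship random effect; returns the fitted backend
    (with ``sigma2_g``, ``sigma2_e`` and ``g_hat`` attributes)."""
    K = getattr(K, "values", K)
    return make_backend("mixed_rf", config).fit(
        np.asarray(X, float), np.asarray(y, float), seed=seed,
        K_tt=np.asarray(K, float))


def fit_blup(Z, y, delta: float | None = None,
             config: ModelConfig | None = None, seed: int = 0):
    """Fit GBLUP on a (standardisable) genotype/feature matrix."""
    from dataclasses import replace

    config = config or ModelConfig()
    if delta is not None:
        config = replace(config, blup_delta=delta)
    return make_backend("blup", config).fit(np.asarray(Z, float),
                                            np.asarray(y, float), seed=seed)
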