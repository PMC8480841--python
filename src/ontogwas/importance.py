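"""Feature importance with response-permutation nulls and empirical FDR.

The null distribution of each feature's importance is built by repeatedly
permuting the response, refitting the model and recording the importance
(100 replicates by default).  The empirical P value is
``(1 + #{null >= observed}) / (1 + n_perm)`` -- one is added to numerator and
denominator so P can never be exactly zero.  Features with ``P < alpha`` in
every cross-validation fold form the consensus selection.

The empirical FDR repeats the whole procedure on a scrambled copy of the
feature matrix and reports the ratio of null to observed consensus counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import as_frame, substream_rng, substream_seed
from .backends import ModelConfig, make_backend
from .models import make_folds
from .ontology import Ontology

logger = logging.getLogger(__name__)

__all__ = [
    "FoldImportance",
    "ImportanceResult",
    "permutation_importance",
    "run_importance_analysis",
    "consensus_features",
    "empirical_fdr",
    "scramble_matrix",
    "enrich_features",
    "compare_top_features",
]


@dataclass
class FoldImportance:
    """Observed importance, permutation null and empirical P for one fold."""

    observed: pd.Series  # feature -> importance
    null: pd.DataFrame = field(repr=False)  # n_perm x features
    pvalues: pd.Series = field(init=False)

    def __post_init__(self):
        n_perm = len(self.null)
        ge = (self.null.to_numpy() >= self.observed.to_numpy()).sum(axis=0)
        self.pvalues = pd.Series((1 + ge) / (1 + n_perm),
                                 index=self.observed.index, name="p")


def permutation_importance(X, y, backend: str = "rf", n_perm: int = 100,
                           seed: int = 0, config: ModelConfig | None = None,
                           K_tt=None) -> FoldImportance:
    """Importance and empirical P for a single fit (single fold).

    The observed importance comes from the model fitted to ``(X, y)``; the
    null from ``n_perm`` refits on permuted copies of ``y``.  Per-replicate
    seeds are derived deterministically from ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float).ravel()
    model = make_backend(backend, config)
    if not hasattr(model, "importances"):
        raise ValueError(f"backend {backend!r} has no importance measure")
    model.fit(X.to_numpy(dtype=float), y, seed=substream_seed(seed, "obs"),
              K_tt=K_tt)
    observed = pd.Series(model.importances(seed=substream_seed(seed, "obsimp")),
                         index=X.columns, name="importance")
    null = np.empty((n_perm, X.shape[1]))
    for r in range(n_perm):
        y_perm = substream_rng(seed, "perm", r).permutation(y)
        m = make_backend(backend, config)
        m.fit(X.to_numpy(dtype=float), y_perm,
              seed=substream_seed(seed, "permfit", r), K_tt=K_tt)
        null[r] = m.importances(seed=substream_seed(seed, "permimp", r))
    return FoldImportance(observed, pd.DataFrame(null, columns=X.columns))


@dataclass
class ImportanceResult:
    """Per-fold importance analysis with consensus selection."""

    importance: pd.DataFrame  # features x folds
    pvalues: pd.DataFrame  # features x folds
    alpha: float
    n_null_replicates: int
    consensus_selected: list[str]
    normalized_importance: pd.Series
    empirical_fdr: float | None = None

    @property
    def mean_importance(self) -> pd.Series:
        return self.importance.mean(axis=1)

    def summary(self) -> str:
        lines = [
            "Permutation-null importance",
            "=" * 44,
            f"features:            {len(self.importance)}",
            f"folds:               {self.importance.shape[1]}",
            f"null replicates:     {self.n_null_replicates}",
            f"alpha:               {self.alpha}",
            f"consensus selected:  {len(self.consensus_selected)}",
        ]
        if self.empirical_fdr is not None:
            lines.append(f"empirical FDR:       {self.empirical_fdr:.4f}")
        for f in self.consensus_selected[:15]:
            lines.append(f"  {f}  (norm. importance "
                         f"{self.normalized_importance[f]:.3f})")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Tidy (feature, fold, importance, p) table."""
        imp = self.importance.stack()
        p = self.pvalues.stack()
        out = pd.DataFrame({"importance": imp, "p": p}).reset_index()
        out.columns = ["feature", "fold", "importance", "p"]
        return out


def consensus_features(per_fold, alpha: float = 0.01,
                       importance: pd.DataFrame | None = None) -> list[str]:
    """Features with ``P < alpha`` in every fold.

    ``per_fold`` is a list of :class:`FoldImportance` or a features x folds
    P-value DataFrame.  Ordering: mean importance descending, ties broken
    lexicographically.
    """
    if isinstance(per_fold, pd.DataFrame):
        pvals = per_fold
        if importance is None:
            importance = pd.DataFrame(0.0, index=pvals.index,
                                      columns=pvals.columns)
    else:
        universes = [tuple(f.pvalues.index) for f in per_fold]
        if len(set(universes)) != 1:
            raise ValueError("per-fold feature universes differ")
        pvals = pd.concat([f.pvalues for f in per_fold], axis=1)
        importance = pd.concat([f.observed for f in per_fold], axis=1)
    selected = pvals.index[(pvals < alpha).all(axis=1)]
    mean_imp = importance.loc[selected].mean(axis=1)
    order = sorted(selected, key=lambda f: (-mean_imp[f], f))
    return order


def _normalize(mean_imp: pd.Series) -> pd.Series:
    lo, hi = float(mean_imp.min()), float(mean_imp.max())
    if hi > lo:
        return (mean_imp - lo) / (hi - lo)
    return pd.Series(0.0, index=mean_imp.index)


def run_importance_analysis(features, y, backend: str = "rf",
                            config: ModelConfig | None = None,
                            n_folds: int = 5, n_perm: int = 100,
                            alpha: float = 0.01, seed: int = 0,
                            kinship=None) -> ImportanceResult:
    """Per-fold permutation importance over a cross-validation split.

    For each fold, the model is fitted to the training split and the
    permutation null is built by permuting the training response.  Fold
    assignment uses the same seeded scheme as model cross-validation, so a
    given root seed yields identical folds in both analyses.
    """
    X = as_frame(features)
    if isinstance(y, pd.Series):
        y = y.loc[X.index].to_numpy(dtype=float)
    else:
        y = np.asarray(y, dtype=float).ravel()
    kin = as_frame(kinship)
    assignment = make_folds(len(y), n_folds, substream_seed(seed, "folds"))
    folds = []
    for k in range(n_folds):
        tr = assignment != k
        K_tt = None
        if kin is not None:
            Karr = np.asarray(kin, dtype=float)
            K_tt = Karr[np.ix_(tr, tr)]
        folds.append(
            permutation_importance(
                X.loc[tr], y[tr], backend=backend, n_perm=n_perm,
                seed=substream_seed(seed, "ifold", k), config=config, K_tt=K_tt,
            )
        )
    imp = pd.concat([f.observed for f in folds], axis=1)
    imp.columns = range(n_folds)
    pvals = pd.concat([f.pvalues for f in folds], axis=1)
    pvals.columns = range(n_folds)
    selected = consensus_features(folds, alpha=alpha)
    return ImportanceResult(
        importance=imp,
        pvalues=pvals,
        alpha=alpha,
        n_null_replicates=n_perm,
        consensus_selected=selected,
        normalized_importance=_normalize(imp.mean(axis=1)),
    )


def scramble_matrix(X: pd.DataFrame, seed: int, how: str = "columns") -> pd.DataFrame:
    """Scramble a feature matrix for the empirical-FDR null.

    ``columns`` permutes each feature column independently across strains
    (destroys feature-phenotype and inter-feature structure, preserves
    marginals); ``rows`` permutes the strain labels jointly.
    """
    if how == "columns":
        out = X.copy()
        for col in X.columns:
            rng = substream_rng(seed, "scramble", str(col))
            out[col] = rng.permutation(X[col].to_numpy())
        return out
    if how == "rows":
        rng = substream_rng(seed, "scramble-rows")
        return pd.DataFrame(X.to_numpy()[rng.permutation(len(X))],
                            index=X.index, columns=X.columns)
    raise ValueError("how must be 'columns' or 'rows'")


def empirical_fdr(features, y, backend: str = "rf",
                  config: ModelConfig | None = None,
                  observed: ImportanceResult | None = None,
                  n_folds: int = 5, n_perm: int = 100, alpha: float = 0.01,
                  seed: int = 0, scramble: str = "columns"):
    """Empirical FDR from a scrambled feature matrix.

    Reruns the full importance pipeline (same folds and permutation counts)
    on a scrambled copy of the features and reports
    ``FDR = n_null_consensus / n_observed_consensus`` capped at 1.0.

    Returns ``(fdr, observed_result, null_result)``.
    """
    X = as_frame(features)
    if observed is None:
        observed = run_importance_analysis(
            X, y, backend=backend, config=config, n_folds=n_folds,
            n_perm=n_perm, alpha=alpha, seed=seed)
    X_null = scramble_matrix(X, seed, how=scramble)
    null_result = run_importance_analysis(
        X_null, y, backend=backend, config=config, n_folds=n_folds,
        n_perm=n_perm, alpha=alpha, seed=seed)
    n_obs = len(observed.consensus_selected)
    n_null = len(null_result.consensus_selected)
    if n_obs == 0:
        if n_null == 0:
            fdr = 0.0
        else:
            warnings.warn("no observed consensus features but a non-empty "
                          "scrambled-matrix selection; FDR reported as 1.0")
            fdr = 1.0
    else:
        fdr = min(n_null / n_obs, 1.0)
    observed.empirical_fdr = fdr
    return fdr, observed, null_result


# ---------------------------------------------------------------------------
# feature-set comparison and enrichment


def enrich_features(gene_set, ont: Ontology, universe) -> pd.DataFrame:
    """Hypergeometric over-representation of each term in a gene selection.

    Propagated annotations are restricted to the universe; the one-sided
    P value is the upper tail of the hypergeometric distribution, with
    Benjamini-Hochberg adjusted values alongside.
    """
    gene_set = set(gene_set)
    universe = set(universe)
    if not gene_set:
        raise ValueError("empty gene set")
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    if not universe & set(ont.genes):
        raise ValueError("universe does not overlap ontology genes")
    M = len(universe)
    N = len(gene_set)
    rows = []
    for term, genes in sorted(ont.propagated_annotations.items()):
        K = len(genes & universe)
        if K == 0:
            continue
        x = len(genes & gene_set)
        p = float(stats.hypergeom.sf(x - 1, M, K, N))
        rows.append((term, K, x, p))
    df = pd.DataFrame(rows, columns=["term", "n_universe", "overlap", "p_raw"])
    df = df.set_index("term")
    from statsmodels.stats.multitest import multipletests

    df["p_bh"] = multipletests(df["p_raw"], method="fdr_bh")[1]
    return df.sort_values(["p_raw", "overlap"], ascending=[True, False])


def compare_top_features(top_a, top_b, universe_size: int,
                         k: int | None = None):
    """Odds ratio and Fisher exact P for overlap of two top-k feature lists.

    The 2x2 table counts membership in A against membership in B over a
    universe of ``universe_size`` features.  The odds ratio uses a Haldane
    0.5 correction when any cell is zero; the two-sided P follows the
    point-probability rule of the exact test.
    """
    top_a, top_b = list(top_a), list(top_b)
    k = k if k is not None else len(top_a)
    if len(top_a) != k or len(top_b) != k:
        raise ValueError(f"both lists must have length k={k}")
    if k > universe_size:
        raise ValueError("k exceeds the universe size")
    a, b = set(top_a), set(top_b)
    both = len(a & b)
    only_a = len(a - b)
    only_b = len(b - a)
    neither = universe_size - len(a | b)
    table = np.array([[both, only_a], [only_b, neither]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if (table == 0).any():
        t = table + 0.5
    else:
        t = table.astype(float)
    odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return float(odds), float(p)
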