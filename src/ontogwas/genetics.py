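"""Burden validation, relationship matrices, heritability and variance explained.

* :func:`burden_test` compares phenotype across strata defined by the number
  of mutated genes in a system, referenced against same-size random gene sets
  drawn from outside the system (one-way ANOVA with Tukey's correction).
* :func:`additive_grm` / :func:`epistatic_grm` build the genomic relationship
  matrix ``K = Z Z' / m`` from standardised genotypes and its Hadamard square
  (pairwise epistasis).
* :func:`estimate_variance_components` fits
  ``y = mu + g_a + g_i + e`` by REML and reports narrow-sense heritability
  ``h2 = sigma2_a / (sigma2_a + sigma2_i + sigma2_e)``.
* :func:`variance_explained` is the in-sample OLS R^2 of a trait on a set of
  gene mutation indicators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from . import lmm
from ._utils import as_frame, substream_rng
from .genotype import GeneMutationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Kinship",
    "BurdenTestResult",
    "HeritabilityEstimate",
    "VarianceExplained",
    "burden_test",
    "additive_grm",
    "epistatic_grm",
    "estimate_variance_components",
    "variance_explained",
]


@dataclass
class Kinship:
    """Strains x strains relatedness matrix."""

    values: pd.DataFrame
    kind: str  # "additive" or "epistatic"
    source: str = ""

    def __post_init__(self):
        v = self.values.to_numpy(dtype=float)
        if v.shape[0] != v.shape[1]:
            raise ValueError("kinship must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("kinship must be symmetric")
        w = linalg.eigvalsh(v)
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise ValueError(f"kinship not PSD (min eigenvalue {w.min():.3g})")

    @property
    def strains(self) -> list[str]:
        return list(self.values.index)

    def write(self, path) -> None:
        self.values.to_csv(path, sep="\t")


def additive_grm(Z, source: str = "") -> Kinship:
    """Additive GRM from a binary strains x SNV matrix.

    Columns are centred and scaled to unit variance (monomorphic columns are
    dropped with a log message) and ``K = Z Z' / m``.
    """
    Z = as_frame(Z) if not isinstance(Z, np.ndarray) else pd.DataFrame(Z)
    Zs, _, _, kept = lmm.standardize_genotypes(Z.to_numpy(dtype=float))
    n_dropped = int((~kept).sum())
    if n_dropped:
        logger.info("dropped %d monomorphic columns from GRM", n_dropped)
    m = Zs.shape[1]
    K = (Zs @ Zs.T) / m
    return Kinship(pd.DataFrame(K, index=Z.index, columns=Z.index),
                   kind="additive", source=source or f"{m} SNVs")


def epistatic_grm(K: Kinship) -> Kinship:
    """Hadamard square of the additive GRM (PSD by the Schur product theorem)."""
    return Kinship(K.values ** 2, kind="epistatic", source=K.source)


# ---------------------------------------------------------------------------
# burden test


@dataclass
class BurdenTestResult:
    """Phenotype stratified by system mutation burden, with a random-set null."""

    groups: pd.DataFrame  # index: bin label; columns n, mean_phenotype
    anova_F: float
    anova_p: float
    tukey: pd.DataFrame  # bin_a, bin_b, difference, p_adj
    random_null: pd.DataFrame = field(repr=False)  # draws x bins, mean phenotype
    system_genes: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "System burden test",
            "=" * 44,
            f"system genes:   {len(self.system_genes)}",
            f"ANOVA:          F = {self.anova_F:.3f}, p = {self.anova_p:.3g}",
            "-" * 44,
            "bin   n      mean phenotype   null mean (random sets)",
        ]
        null_means = self.random_null.mean(axis=0)
        for b, row in self.groups.iterrows():
            nm = null_means.get(b, np.nan)
            lines.append(f"{b:<5} {int(row['n']):<6} {row['mean_phenotype']:<16.4f} "
                         f"{nm:.4f}")
        return "\n".join(lines)


def _merge_small_bins(burden: np.ndarray, min_group_size: int) -> np.ndarray:
    """Merge burden bins with too few strains into the nearest lower bin."""
    levels = sorted(np.unique(burden))
    assign = {lvl: lvl for lvl in levels}

    def counts():
        c: dict = {}
        for lvl in levels:
            c[assign[lvl]] = c.get(assign[lvl], 0) + int((burden == lvl).sum())
        return c

    changed = True
    while changed:
        changed = False
        c = counts()
        for b in sorted(set(assign.values()), reverse=True):
            lower = [bb for bb in set(assign.values()) if bb < b]
            if c[b] < min_group_size and lower:
                tgt = max(lower)
                for lvl in levels:
                    if assign[lvl] == b:
                        assign[lvl] = tgt
                changed = True
                break
    return np.array([assign[b] for b in burden])


def burden_test(genes: GeneMutationMatrix, system_genes, pheno: pd.Series,
                n_random: int = 1000, seed: int = 0,
                min_group_size: int = 5) -> BurdenTestResult:
    """One-way ANOVA (with Tukey HSD) of phenotype across burden strata.

    Strains are binned by their count of mutated genes within the system;
    bins smaller than ``min_group_size`` are merged downward.  The null
    reference re-draws ``n_random`` same-size gene sets from genes outside
    the system and records the per-bin mean phenotype of each draw.
    """
    system_genes = sorted(set(system_genes))
    missing = set(system_genes) - set(genes.genes)
    if missing:
        raise ValueError(f"system genes absent from matrix: {sorted(missing)[:5]}")
    pheno = pd.Series(pheno).dropna().astype(float)
    shared = genes.values.index.intersection(pheno.index)
    G = genes.values.loc[shared]
    y = pheno.loc[shared].to_numpy()

    burden = G[system_genes].sum(axis=1).to_numpy()
    merged = _merge_small_bins(burden, min_group_size)
    bins = sorted(np.unique(merged))
    if len(bins) < 2:
        raise ValueError("system burden non-informative: fewer than 2 usable bins")

    def _label(b):
        members = sorted(np.unique(burden[merged == b]))
        return str(b) if len(members) == 1 else f"{b}+"

    labels = {b: _label(b) for b in bins}
    samples = [y[merged == b] for b in bins]
    F, p = stats.f_oneway(*samples)
    hsd = stats.tukey_hsd(*samples)
    rows = []
    for i, bi in enumerate(bins):
        for j, bj in enumerate(bins):
            if j <= i:
                continue
            rows.append((labels[bi], labels[bj],
                         float(np.mean(samples[j]) - np.mean(samples[i])),
                         float(hsd.pvalue[i, j])))
    tukey = pd.DataFrame(rows, columns=["bin_a", "bin_b", "difference", "p_adj"])

    groups = pd.DataFrame(
        {"n": [len(s) for s in samples],
         "mean_phenotype": [float(np.mean(s)) for s in samples]},
        index=pd.Index([labels[b] for b in bins], name="burden"),
    )

    outside = [g for g in genes.genes if g not in set(system_genes)]
    if len(outside) < len(system_genes):
        raise ValueError("not enough genes outside the system for the null draws")
    rng = substream_rng(seed, "burden-null")
    Gout = G[outside].to_numpy()
    null = np.full((n_random, len(bins)), np.nan)
    # bin edges are those of the real system so distributions are comparable
    cut = {b: (merged == b) for b in bins}
    thresholds = bins  # merged burden values
    for d in range(n_random):
        pick = rng.choice(len(outside), size=len(system_genes), replace=False)
        rb = Gout[:, pick].sum(axis=1)
        rb_m = np.array([max([b for b in thresholds if b <= v], default=thresholds[0])
                         for v in rb])
        for jx, b in enumerate(bins):
            mask = rb_m == b
            if mask.any():
                null[d, jx] = float(y[mask].mean())
    random_null = pd.DataFrame(null, columns=[labels[b] for b in bins])
    return BurdenTestResult(groups, float(F), float(p), tukey, random_null,
                            system_genes=system_genes)


# ---------------------------------------------------------------------------
# heritability


@dataclass
class HeritabilityEstimate:
    """Variance decomposition into additive, epistatic and residual parts."""

    sigma2_a: float
    sigma2_i: float
    sigma2_e: float
    snv_set: str = ""
    method: str = "REML (Nelder-Mead over log-variances)"
    converged: bool = True

    @property
    def h2(self) -> float:
        total = self.sigma2_a + self.sigma2_i + self.sigma2_e
        return self.sigma2_a / total if total > 0 else 0.0

    def summary(self) -> str:
        return "\n".join([
            "Narrow-sense heritability (REML)",
            "=" * 44,
            f"SNV set:       {self.snv_set or '-'}",
            f"sigma2_a:      {self.sigma2_a:.5g}",
            f"sigma2_i:      {self.sigma2_i:.5g}",
            f"sigma2_e:      {self.sigma2_e:.5g}",
            f"h2:            {self.h2:.4f}",
            f"converged:     {self.converged}",
        ])

    def to_dict(self) -> dict:
        return {"sigma2_a": self.sigma2_a, "sigma2_i": self.sigma2_i,
                "sigma2_e": self.sigma2_e, "h2": self.h2,
                "snv_set": self.snv_set, "method": self.method,
                "converged": self.converged}


def estimate_variance_components(y: pd.Series, K_add: Kinship,
                                 K_epi: Kinship | None = None) -> HeritabilityEstimate:
    """REML variance components for ``y = mu + g_a [+ g_i] + e``."""
    y = pd.Series(y).dropna().astype(float)
    strains = [s for s in K_add.strains if s in set(y.index)]
    yv = y.loc[strains].to_numpy()
    if np.var(yv) == 0:
        raise ValueError("constant phenotype: variance components undefined")
    Ks = [K_add.values.loc[strains, strains].to_numpy()]
    if K_epi is not None:
        Ks.append(K_epi.values.loc[strains, strains].to_numpy())
    variances, s2e, converged = lmm.reml_multi(yv, Ks, check=False)
    s2a = float(variances[0])
    s2i = float(variances[1]) if K_epi is not None else 0.0
    return HeritabilityEstimate(s2a, s2i, float(s2e), snv_set=K_add.source,
                                converged=converged)


# ---------------------------------------------------------------------------
# variance explained by a gene set


@dataclass
class VarianceExplained:
    gene_set: list[str]
    r2: float
    h2_reference: HeritabilityEstimate | None = None

    def summary(self) -> str:
        lines = [
            "Variance explained by gene indicators (in-sample OLS)",
            "=" * 52,
            f"genes:   {len(self.gene_set)}",
            f"R2:      {self.r2:.4f}",
        ]
        if self.h2_reference is not None:
            lines.append(f"h2 ref:  {self.h2_reference.h2:.4f}")
        return "\n".join(lines)


def variance_explained(genes: GeneMutationMatrix, gene_set, y: pd.Series,
                       h2_reference: HeritabilityEstimate | None = None,
                       ) -> VarianceExplained:
    """In-sample OLS R^2 of the trait on the selected gene indicator columns."""
    gene_set = sorted(set(gene_set))
    if not gene_set:
        raise ValueError("empty gene set")
    missing = set(gene_set) - set(genes.genes)
    if missing:
        raise ValueError(f"genes absent from matrix: {sorted(missing)[:5]}")
    y = pd.Series(y).dropna().astype(float)
    shared = genes.values.index.intersection(y.index)
    X = genes.values.loc[shared, gene_set].to_numpy(dtype=float)
    yv = y.loc[shared].to_numpy()
    n = len(yv)
    if len(gene_set) >= n:
        raise ValueError(f"more genes ({len(gene_set)}) than strains ({n})")
    design = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(design, yv, rcond=None)  # pseudoinverse on collinearity
    resid = yv - design @ beta
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return VarianceExplained(gene_set, float(np.clip(r2, 0.0, 1.0)),
                             h2_reference=h2_reference)
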