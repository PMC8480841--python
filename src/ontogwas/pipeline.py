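"""End-to-end orchestration: config file in, manifest out.

Stages run in a fixed order -- load, matrices, ontotype, train, importance,
fdr, burden, heritability -- with every source of randomness derived from the
single config seed via named substreams, so a rerun with the same config and
seed is bit-identical.  The manifest records package version, seeds, input
digests and every stage output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._utils import substream_seed
from .backends import ModelConfig
from .genetics import (additive_grm, burden_test, epistatic_grm,
                       estimate_variance_components, variance_explained)
from .genotype import DEFAULT_EFFECT_FILTER, collapse_to_genes, read_variants
from .importance import empirical_fdr, run_importance_analysis
from .models import TraitModel, read_phenotypes
from .ontology import join_under_root, load_ontology, prune_ontology
from .ontotype import compute_ontotype

logger = logging.getLogger(__name__)

STAGES = ["load", "matrices", "ontotype", "train", "importance", "fdr",
          "burden", "heritability"]

__all__ = ["RunConfig", "run_pipeline", "PipelineError", "STAGES"]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    genotypes: str
    phenotypes: str
    ontology_structure: str
    outdir: str
    ontology_annotations: str | None = None
    feature_level: str = "ontotype"  # snv | gene | ontotype
    backend: str = "mixed_rf"
    traits: list[str] | None = None
    seed: int = 0
    alpha: float = 0.01
    n_perm: int = 100
    n_random_sets: int = 1000
    n_folds: int = 5
    top_systems: int = 10
    max_key_genes: int = 29
    effect_filter: list[str] = field(
        default_factory=lambda: sorted(DEFAULT_EFFECT_FILTER))
    missing_policy: str = "ref"
    scramble: str = "columns"
    model: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.feature_level not in ("snv", "gene", "ontotype"):
            raise ValueError(f"unknown feature level {self.feature_level!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def model_config(self) -> ModelConfig:
        return ModelConfig(**self.model)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _dump_json(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
    return str(path)


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    raise TypeError(f"not JSON serialisable: {type(v)}")


def run_pipeline(cfg: RunConfig, through: str = "heritability") -> dict:
    """Run the pipeline up to (and including) stage ``through``.

    Returns the manifest dict (also written to ``<outdir>/manifest.json``).
    """
    if through not in STAGES:
        raise ValueError(f"unknown stage {through!r}; stages are {STAGES}")
    last = STAGES.index(through)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "ontogwas",
        "version": __version__,
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "inputs": {},
        "stages": {},
    }
    state: dict = {}

    def _stage(name):
        return STAGES.index(name) <= last

    try:
        _run_load(cfg, state, manifest)
        if _stage("matrices"):
            _run_matrices(cfg, state, manifest, outdir)
        if _stage("ontotype"):
            _run_ontotype(cfg, state, manifest, outdir)
        if _stage("train"):
            _run_train(cfg, state, manifest, outdir)
        if _stage("importance"):
            _run_importance(cfg, state, manifest, outdir)
        if _stage("fdr"):
            _run_fdr(cfg, state, manifest, outdir)
        if _stage("burden"):
            _run_burden(cfg, state, manifest, outdir)
        if _stage("heritability"):
            _run_heritability(cfg, state, manifest, outdir)
    except PipelineError:
        raise
    except Exception as err:
        stage = state.get("_current", "load")
        raise PipelineError(f"stage {stage!r} failed: {err}") from err

    _dump_json(manifest, outdir / "manifest.json")
    return manifest


# -- stages -----------------------------------------------------------------


def _run_load(cfg, state, manifest):
    state["_current"] = "load"
    for key in ("genotypes", "phenotypes", "ontology_structure",
                "ontology_annotations"):
        path = getattr(cfg, key)
        if path:
            manifest["inputs"][key] = {"path": str(path), "sha256": _sha256(path)}
    state["genotypes"] = read_variants(
        cfg.genotypes, effect_filter=set(cfg.effect_filter),
        missing_policy=cfg.missing_policy)
    ont = load_ontology(cfg.ontology_structure, cfg.ontology_annotations)
    if len(ont.roots) > 1:
        ont = join_under_root(ont)
    state["ontology"] = prune_ontology(ont)
    state["phenotypes"] = read_phenotypes(cfg.phenotypes)
    traits = cfg.traits or list(state["phenotypes"].columns)
    missing = [t for t in traits if t not in state["phenotypes"].columns]
    if missing:
        raise ValueError(f"traits not in phenotype table: {missing}")
    state["traits"] = traits
    manifest["stages"]["load"] = {
        "n_strains": len(state["genotypes"].strains),
        "n_variants": len(state["genotypes"].variants),
        "n_terms": len(state["ontology"].terms),
        "traits": traits,
    }


def _run_matrices(cfg, state, manifest, outdir):
    state["_current"] = "matrices"
    state["genes"] = collapse_to_genes(state["genotypes"])
    p1 = outdir / "snv_matrix.tsv"
    p2 = outdir / "gene_matrix.tsv"
    state["genotypes"].values.to_csv(p1, sep="\t")
    state["genes"].values.to_csv(p2, sep="\t")
    manifest["stages"]["matrices"] = {
        "snv_matrix": str(p1), "gene_matrix": str(p2),
        "n_genes": len(state["genes"].genes),
    }


def _run_ontotype(cfg, state, manifest, outdir):
    state["_current"] = "ontotype"
    ot = compute_ontotype(state["genes"], state["ontology"])
    state["ontotypes"] = ot
    p1 = outdir / "ontotype_matrix.tsv"
    p2 = outdir / "term_meta.tsv"
    ot.write(p1, p2)
    manifest["stages"]["ontotype"] = {
        "ontotype_matrix": str(p1), "term_meta": str(p2),
        "n_terms": len(ot.terms),
    }


def _features(cfg, state) -> pd.DataFrame:
    return {
        "snv": state["genotypes"].values,
        "gene": state["genes"].values,
        "ontotype": state["ontotypes"].values,
    }[cfg.feature_level]


def _kinship(cfg, state):
    if "kinship" not in state:
        state["kinship"] = additive_grm(state["genotypes"].values,
                                        source=f"{cfg.feature_level} model SNVs")
    return state["kinship"]


def _run_train(cfg, state, manifest, outdir):
    state["_current"] = "train"
    features = _features(cfg, state)
    kin = _kinship(cfg, state) if cfg.backend in ("mixed_rf",) else None
    results = {}
    for trait in state["traits"]:
        model = TraitModel.from_matrices(
            features, state["phenotypes"], trait, backend=cfg.backend,
            kinship=kin, config=cfg.model_config())
        res = model.fit(n_folds=cfg.n_folds,
                        seed=substream_seed(cfg.seed, "train", trait))
        results[trait] = res
        logger.info("trait %s: mean R2 = %.4f", trait, res.mean_r2)
    state["cv_results"] = results
    path = outdir / "cv_results.json"
    _dump_json({t: r.to_dict() for t, r in results.items()}, path)
    manifest["stages"]["train"] = {
        "cv_results": str(path),
        "mean_r2": {t: r.mean_r2 for t, r in results.items()},
    }


def _run_importance(cfg, state, manifest, outdir):
    state["_current"] = "importance"
    features = _features(cfg, state)
    kin = _kinship(cfg, state) if cfg.backend in ("mixed_rf",) else None
    state["importance"] = {}
    out = {}
    for trait in state["traits"]:
        y = state["phenotypes"][trait].dropna()
        shared = features.index.intersection(y.index)
        res = run_importance_analysis(
            features.loc[shared], y.loc[shared], backend=cfg.backend,
            config=cfg.model_config(), n_folds=cfg.n_folds, n_perm=cfg.n_perm,
            alpha=cfg.alpha, seed=substream_seed(cfg.seed, "train", trait),
            kinship=kin.values.loc[shared, shared] if kin is not None else None)
        state["importance"][trait] = res
        p = outdir / f"importance_{trait}.tsv"
        res.to_frame().to_csv(p, sep="\t", index=False)
        out[trait] = {"table": str(p),
                      "n_consensus": len(res.consensus_selected),
                      "consensus": res.consensus_selected}
    manifest["stages"]["importance"] = out


def _run_fdr(cfg, state, manifest, outdir):
    state["_current"] = "fdr"
    features = _features(cfg, state)
    kin = _kinship(cfg, state) if cfg.backend in ("mixed_rf",) else None
    out = {}
    for trait in state["traits"]:
        y = state["phenotypes"][trait].dropna()
        shared = features.index.intersection(y.index)
        fdr, obs, null = empirical_fdr(
            features.loc[shared], y.loc[shared], backend=cfg.backend,
            config=cfg.model_config(), observed=state["importance"][trait],
            n_folds=cfg.n_folds, n_perm=cfg.n_perm, alpha=cfg.alpha,
            seed=substream_seed(cfg.seed, "train", trait), scramble=cfg.scramble)
        out[trait] = {
            "empirical_fdr": fdr,
            "n_observed": len(obs.consensus_selected),
            "n_null": len(null.consensus_selected),
        }
    state["fdr"] = out
    path = outdir / "empirical_fdr.json"
    _dump_json(out, path)
    manifest["stages"]["fdr"] = {"report": str(path), **out}


def _top_system_genes(state, cfg, trait):
    """Genes of the top consensus systems, ranked for variance accounting."""
    res = state["importance"][trait]
    prop = state["ontology"].propagated_annotations
    matrix_genes = set(state["genes"].genes)
    if cfg.feature_level == "ontotype":
        top_terms = res.consensus_selected[:cfg.top_systems]
        genes = set()
        for t in top_terms:
            genes |= prop.get(t, frozenset()) & matrix_genes
    else:
        top_terms = []
        genes = set(res.consensus_selected[:cfg.max_key_genes]) & matrix_genes
    y = state["phenotypes"][trait].dropna()
    shared = state["genes"].values.index.intersection(y.index)
    G = state["genes"].values.loc[shared]
    yv = y.loc[shared]
    ranked = sorted(
        genes,
        key=lambda g: (-abs(np.corrcoef(G[g], yv)[0, 1])
                       if G[g].nunique() > 1 else 0.0, g),
    )
    return top_terms, ranked[:cfg.max_key_genes]


def _run_burden(cfg, state, manifest, outdir):
    state["_current"] = "burden"
    out = {}
    prop = state["ontology"].propagated_annotations
    matrix_genes = set(state["genes"].genes)
    for trait in state["traits"]:
        y = state["phenotypes"][trait].dropna()
        res = state["importance"][trait]
        systems = (res.consensus_selected[:cfg.top_systems]
                   if cfg.feature_level == "ontotype" else [])
        trait_out = {}
        for term in systems:
            genes_in = sorted(prop.get(term, frozenset()) & matrix_genes)
            if not genes_in:
                continue
            try:
                bt = burden_test(state["genes"], genes_in, y,
                                 n_random=cfg.n_random_sets,
                                 seed=substream_seed(cfg.seed, "burden", trait,
                                                     term))
            except ValueError as err:
                trait_out[term] = {"skipped": str(err)}
                continue
            trait_out[term] = {
                "anova_F": bt.anova_F, "anova_p": bt.anova_p,
                "groups": bt.groups.reset_index().to_dict("records"),
            }
        out[trait] = trait_out
    path = outdir / "burden_tests.json"
    _dump_json(out, path)
    state["burden"] = out
    manifest["stages"]["burden"] = {"report": str(path)}


def _run_heritability(cfg, state, manifest, outdir):
    state["_current"] = "heritability"
    K_add = _kinship(cfg, state)
    K_epi = epistatic_grm(K_add)
    out = {}
    for trait in state["traits"]:
        y = state["phenotypes"][trait].dropna()
        est = estimate_variance_components(y, K_add, K_epi)
        _, key_genes = _top_system_genes(state, cfg, trait)
        entry = {"heritability": est.to_dict(), "key_genes": key_genes}
        if key_genes:
            ve = variance_explained(state["genes"], key_genes, y,
                                    h2_reference=est)
            entry["variance_explained_r2"] = ve.r2
        out[trait] = entry
    path = outdir / "heritability.json"
    _dump_json(out, path)
    state["heritability"] = out
    manifest["stages"]["heritability"] = {"report": str(path)}
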