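"""Synthetic structured populations, ontologies and phenotypes.

The generator emulates the statistical setting the pipeline is built for: a
haploid population of natural isolates split into differentiated
subpopulations (Balding-Nichols allele-frequency drift), binary
non-synonymous SNV calls mapped to genes, a rooted DAG ontology over those
genes, and a quantitative growth phenotype driven by mutation burden in
planted causal systems plus a polygenic background, subpopulation offsets
and Gaussian noise.  A truth record makes every run checkable end to end.

Default condition choices (a structured population of 500 isolates over
3 subpopulations at drift 0.15; 3000 SNVs over 600 genes; a 150-term DAG;
target heritability 0.4 with modest structure confounding) are documented in
the methods note.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._utils import substream_rng
from .genotype import GeneMutationMatrix, GenotypeMatrix, VariantAnnotation, \
    collapse_to_genes
from .ontology import Ontology, prune_ontology
from .ontotype import OntotypeMatrix, compute_ontotype

__all__ = [
    "SimulationConfig",
    "simulate_population",
    "simulate_ontology",
    "simulate_phenotype",
    "simulate_study",
    "SimulatedStudy",
]

TRAIT_NAME = "growth"


@dataclass
class SimulationConfig:
    n_strains: int = 500
    n_subpops: int = 3
    differentiation: float = 0.15  # Balding-Nichols drift parameter in (0,1)
    n_snvs: int = 3000
    n_genes: int = 600
    snv_per_gene: str = "uniform"  # each SNV picks a gene uniformly (~Poisson sizes)
    ontology_shape: tuple = (150, 4, 3)  # (n_terms, depth, branching)
    planted_systems: list = field(default_factory=lambda: [(None, 0.5, -1)])
    # (term or None for auto-pick, effect size per mutated gene, sign)
    target_h2: float = 0.4
    structure_effect: float = 0.3  # variance of subpopulation phenotype offsets
    polygenic_fraction: float = 0.1
    polygenic_sd: float = 0.1
    nonsense_fraction: float = 0.1
    seed: int = 0

    def validate(self):
        if min(self.n_strains, self.n_subpops, self.n_snvs, self.n_genes) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0 < self.differentiation < 1:
            raise ValueError("differentiation must be in (0, 1)")
        if not 0 <= self.target_h2 <= 1:
            raise ValueError("target_h2 must be in [0, 1]")
        n_terms, depth, branching = self.ontology_shape
        if n_terms < depth + 1 or depth < 1 or branching < 1:
            raise ValueError(f"infeasible ontology shape {self.ontology_shape}")


# ---------------------------------------------------------------------------
# population


def simulate_population(cfg: SimulationConfig):
    """Haploid binary SNV calls in a subdivided population.

    Ancestral allele frequencies are Uniform(0.05, 0.5); each subpopulation's
    frequency is drawn from the Balding-Nichols beta distribution with drift
    parameter ``differentiation``.  Returns ``(GenotypeMatrix, labels)``.
    """
    cfg.validate()
    rng = substream_rng(cfg.seed, "population")
    F = cfg.differentiation
    p_anc = rng.uniform(0.05, 0.5, size=cfg.n_snvs)
    a = p_anc * (1 - F) / F
    b = (1 - p_anc) * (1 - F) / F
    p_sub = rng.beta(a, b, size=(cfg.n_subpops, cfg.n_snvs))
    labels = np.arange(cfg.n_strains) % cfg.n_subpops
    calls = (rng.random((cfg.n_strains, cfg.n_snvs)) < p_sub[labels]).astype(np.int8)

    strains = [f"S{i:04d}" for i in range(cfg.n_strains)]
    gene_ids = [f"G{i:04d}" for i in range(cfg.n_genes)]
    gene_of = rng.integers(0, cfg.n_genes, size=cfg.n_snvs)
    is_nonsense = rng.random(cfg.n_snvs) < cfg.nonsense_fraction
    variants = [f"v{j:06d}" for j in range(cfg.n_snvs)]
    annotations = {
        variants[j]: VariantAnnotation(
            variant_id=variants[j], chrom="chrI", pos=j + 1,
            ref_allele="A", alt_allele="G",
            gene=gene_ids[gene_of[j]],
            effect_class="nonsense" if is_nonsense[j] else "missense",
        )
        for j in range(cfg.n_snvs)
    }
    values = pd.DataFrame(calls, index=pd.Index(strains, name="strain"),
                          columns=variants)
    gm = GenotypeMatrix(values, annotations)
    return gm, pd.Series(labels, index=values.index, name="subpop")


# ---------------------------------------------------------------------------
# ontology


def simulate_ontology(cfg: SimulationConfig) -> Ontology:
    """Random rooted DAG honouring (n_terms, depth, branching); genes at leaves.

    Level sizes grow geometrically with the branching factor; every term has
    a parent in the level above (plus an occasional second parent, making the
    graph a DAG rather than a tree) and every gene attaches to at least one
    leaf, so every gene is reachable from the root.
    """
    cfg.validate()
    rng = substream_rng(cfg.seed, "ontology")
    n_terms, depth, branching = cfg.ontology_shape
    n_internal = n_terms - 1  # excluding the root
    weights = np.array([float(branching) ** d for d in range(depth)])
    sizes = np.maximum(1, np.round(n_internal * weights / weights.sum())).astype(int)
    # fix rounding drift on the deepest (leaf) level
    sizes[-1] += n_internal - sizes.sum()
    if sizes[-1] < 1:
        raise ValueError(f"infeasible ontology shape {cfg.ontology_shape}")

    root = "ROOT"
    edges: list[tuple[str, str]] = []
    levels: list[list[str]] = [[root]]
    counter = 0
    for d in range(depth):
        level = []
        for _ in range(sizes[d]):
            term = f"T{counter:04d}"
            counter += 1
            parent = levels[-1][rng.integers(0, len(levels[-1]))]
            edges.append((term, parent))
            if len(levels[-1]) > 1 and rng.random() < 0.2:
                others = [t for t in levels[-1] if t != parent]
                edges.append((term, others[rng.integers(0, len(others))]))
            level.append(term)
        levels.append(level)

    leaves = levels[-1]
    gene_ids = [f"G{i:04d}" for i in range(cfg.n_genes)]
    annotations: dict[str, set] = {t: set() for t in leaves}
    for g in gene_ids:
        leaf = leaves[rng.integers(0, len(leaves))]
        annotations[leaf].add(g)
        if len(leaves) > 1 and rng.random() < 0.1:
            others = [t for t in leaves if t != leaf]
            annotations[others[rng.integers(0, len(others))]].add(g)
    return Ontology(edges, annotations,
                    {t: "data-driven" for lv in levels for t in lv})


# ---------------------------------------------------------------------------
# phenotype


def _resolve_planted(planted, ont: Ontology, matrix_genes: set,
                     rng: np.random.Generator):
    prop = ont.propagated_annotations
    resolved = []
    candidates = sorted(
        t for t, s in prop.items()
        if t not in ont.roots and 8 <= len(s & matrix_genes) <= 60
    )
    for term, effect, sign in planted:
        if term is None:
            if not candidates:
                raise ValueError("no candidate term of suitable size to plant")
            term = candidates[rng.integers(0, len(candidates))]
            candidates = [t for t in candidates if t != term]
        elif term not in prop:
            raise ValueError(f"planted term {term!r} not in the ontology")
        resolved.append((term, float(effect), int(np.sign(sign) or 1)))
    return resolved


def simulate_phenotype(genes: GeneMutationMatrix, ont: Ontology,
                       cfg: SimulationConfig, subpop_labels: pd.Series | None = None):
    """Phenotype = planted system burden + polygenic background + structure + noise.

    The Gaussian noise variance is solved so that the realised genetic
    fraction of the total variance matches ``target_h2``; the truth record
    stores the planted terms, effect sizes and realised variance fractions.
    Returns ``(phenotypes, truth)`` where phenotypes is a strains x 1
    DataFrame (trait ``growth``, in colony-area-like pixel units).
    """
    cfg.validate()
    rng = substream_rng(cfg.seed, "phenotype")
    G = genes.values
    n = len(G)
    prop = ont.propagated_annotations
    matrix_genes = set(genes.genes)

    genetic = np.zeros(n)
    planted_truth = []
    if cfg.target_h2 > 0:
        planted = _resolve_planted(cfg.planted_systems or [], ont, matrix_genes, rng)
        for term, effect, sign in planted:
            term_genes = sorted(prop[term] & matrix_genes)
            burden = G[term_genes].sum(axis=1).to_numpy(dtype=float)
            genetic += sign * effect * burden
            planted_truth.append({
                "term": term, "effect": effect, "sign": sign,
                "n_genes": len(term_genes),
                "burden_variance": float(np.var(burden)),
            })
        n_poly = max(1, int(round(cfg.polygenic_fraction * len(genes.genes))))
        poly_genes = sorted(rng.choice(genes.genes, size=n_poly, replace=False))
        poly_effects = rng.normal(0.0, cfg.polygenic_sd, size=n_poly)
        genetic += G[poly_genes].to_numpy(dtype=float) @ poly_effects
        if np.var(genetic) == 0:
            raise ValueError("zero genetic variance but target_h2 > 0")
    else:
        poly_genes, poly_effects = [], np.array([])

    structure = np.zeros(n)
    offsets = {}
    if subpop_labels is not None and cfg.structure_effect > 0:
        pops = sorted(pd.Series(subpop_labels).unique())
        offs = rng.normal(0.0, np.sqrt(cfg.structure_effect), size=len(pops))
        offsets = {int(p): float(o) for p, o in zip(pops, offs)}
        structure = pd.Series(subpop_labels).map(offsets).to_numpy()

    v_gen = float(np.var(genetic))
    v_str = float(np.var(structure))
    if cfg.target_h2 > 0:
        v_noise = v_gen * (1 - cfg.target_h2) / cfg.target_h2 - v_str
        if v_noise <= 0:
            warnings.warn(
                "structure variance too large for target_h2; noise floored and "
                "the realised heritability will undershoot the target")
            v_noise = 0.01 * v_gen
    else:
        v_noise = 1.0 if (v_gen + v_str) == 0 else (v_gen + v_str)
    noise = rng.normal(0.0, np.sqrt(v_noise), size=n)

    y = genetic + structure + noise
    realized_h2 = v_gen / (v_gen + v_str + float(np.var(noise))) if v_gen else 0.0
    # cosmetic rescale to colony-area-like pixel counts
    scale = 800.0 / max(np.std(y), 1e-12)
    y_px = 5000.0 + scale * (y - y.mean())
    pheno = pd.DataFrame({TRAIT_NAME: y_px}, index=G.index)

    truth = {
        "planted_systems": planted_truth,
        "polygenic_genes": list(poly_genes),
        "polygenic_effects": [float(v) for v in poly_effects],
        "subpop_offsets": offsets,
        "target_h2": cfg.target_h2,
        "realized_h2": float(realized_h2),
        "variance_components": {
            "genetic": v_gen, "structure": v_str, "noise": float(np.var(noise)),
        },
        "trait": TRAIT_NAME,
        "phenotype_scale": float(scale),
    }
    return pheno, truth


# ---------------------------------------------------------------------------
# end-to-end study


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    genotypes: GenotypeMatrix
    subpops: pd.Series
    genes: GeneMutationMatrix
    ontology: Ontology  # pruned, rooted
    ontotypes: OntotypeMatrix
    phenotypes: pd.DataFrame
    truth: dict

    def write(self, outdir) -> dict:
        """Emit the TSV dialects the pipeline reads, plus the truth record."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genotypes": outdir / "genotypes.tsv",
            "ontology": outdir / "ontology_edges.tsv",
            "phenotypes": outdir / "phenotypes.tsv",
            "truth": outdir / "truth.json",
        }
        long = self.genotypes.values.stack()
        long = long[long > 0].reset_index()
        long.columns = ["strain_id", "variant_id", "value"]
        ann = self.genotypes.annotation_frame()
        long["gene"] = long["variant_id"].map(ann["gene"])
        long["effect"] = long["variant_id"].map(ann["effect_class"])
        long[["strain_id", "variant_id", "gene", "effect", "value"]].to_csv(
            paths["genotypes"], sep="\t", index=False)
        self.ontology.write_edgelist(paths["ontology"])
        self.phenotypes.to_csv(paths["phenotypes"], sep="\t")
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=2)
        return {k: str(v) for k, v in paths.items()}


def simulate_study(cfg: SimulationConfig | None = None, **overrides) -> SimulatedStudy:
    """Generate a full study: population, ontology, ontotypes and phenotype."""
    if cfg is None:
        cfg = SimulationConfig(**overrides)
    elif overrides:
        cfg = SimulationConfig(**{**asdict(cfg), **overrides})
    genotypes, subpops = simulate_population(cfg)
    genes = collapse_to_genes(genotypes)
    ont = prune_ontology(simulate_ontology(cfg))
    ontotypes = compute_ontotype(genes, ont)
    pheno, truth = simulate_phenotype(genes, ont, cfg, subpop_labels=subpops)
    truth["config"] = asdict(cfg)
    return SimulatedStudy(cfg, genotypes, subpops, genes, ont, ontotypes,
                          pheno, truth)
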