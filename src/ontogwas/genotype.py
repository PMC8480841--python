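"""Binary SNV presence matrices and the OR-gate gene matrix.

Variants enter either from a VCF 4.x with SnpEff-style ``ANN`` annotations or
from a long-format annotation table.  Only coding variants in the requested
effect classes (default: missense and nonsense) are retained.  Genotypes are
encoded as presence/absence of a non-reference allele: the isolates are
treated as haploid-like, so ``0/1``, ``1/1`` and ``1`` all score 1.

Gene-level scores collapse a gene's variant columns with an OR gate: a gene
scores 1 in a strain when at least one qualifying variant is present, and the
maximum score for any gene is 1 no matter how many variants it carries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariantAnnotation",
    "GenotypeMatrix",
    "GeneMutationMatrix",
    "read_variants",
    "collapse_to_genes",
    "classify_effect",
    "DEFAULT_EFFECT_FILTER",
]

EFFECT_CLASSES = ("missense", "nonsense", "synonymous", "other")
DEFAULT_EFFECT_FILTER = frozenset({"missense", "nonsense"})


def classify_effect(effect: str) -> str:
    """Map a SnpEff effect string onto {missense, nonsense, synonymous, other}."""
    e = (effect or "").lower()
    if "missense" in e:
        return "missense"
    if "stop_gained" in e or "nonsense" in e:
        return "nonsense"
    if "synonymous" in e or "stop_retained" in e:
        return "synonymous"
    return "other"


@dataclass(frozen=True)
class VariantAnnotation:
    variant_id: str
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    gene: str
    effect_class: str

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: position must be >= 1")
        if self.alt_allele == self.ref_allele:
            raise ValueError(f"{self.variant_id}: alt equals ref")
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(f"{self.variant_id}: unknown effect {self.effect_class!r}")


@dataclass
class GenotypeMatrix:
    """Strains x variants binary presence matrix plus per-variant annotation."""

    values: pd.DataFrame  # int8, strains in rows
    annotations: dict[str, VariantAnnotation] = field(repr=False)

    def __post_init__(self):
        v = self.values
        if not v.index.is_unique or not v.columns.is_unique:
            raise ValueError("strain / variant labels must be unique")
        arr = v.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("genotype values must be binary")
        missing = [c for c in v.columns if c not in self.annotations]
        if missing:
            raise ValueError(f"variants without annotation: {missing[:5]}")

    @property
    def strains(self) -> list[str]:
        return list(self.values.index)

    @property
    def variants(self) -> list[str]:
        return list(self.values.columns)

    def to_frame(self) -> pd.DataFrame:
        return self.values.copy()

    def annotation_frame(self) -> pd.DataFrame:
        rows = [vars(self.annotations[v]) for v in self.variants]
        return pd.DataFrame(rows).set_index("variant_id")


@dataclass
class GeneMutationMatrix:
    """Strains x genes binary matrix (OR-collapsed over each gene's variants)."""

    values: pd.DataFrame

    @property
    def strains(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# reading


def read_variants(
    source,
    effect_filter=DEFAULT_EFFECT_FILTER,
    missing_policy: str = "ref",
) -> GenotypeMatrix:
    """Read annotated variants into a binary strains x variants matrix.

    Parameters
    ----------
    source
        VCF (``.vcf``/``.vcf.gz``, needs per-sample GT and SnpEff ``ANN``
        INFO) or a long TSV with header columns
        ``strain_id, variant_id, gene, effect, value``.
    effect_filter
        Effect classes to retain (default missense + nonsense).
    missing_policy
        ``"ref"`` scores missing genotypes 0 (logged); ``"drop"`` drops any
        variant with a missing call.
    """
    effect_filter = frozenset(effect_filter)
    if missing_policy not in ("ref", "drop"):
        raise ValueError("missing_policy must be 'ref' or 'drop'")
    p = str(source)
    if p.endswith(".vcf") or p.endswith(".vcf.gz") or p.endswith(".vcf.bgz"):
        return _read_vcf(source, effect_filter, missing_policy)
    return _read_tsv(source, effect_filter)


def _read_vcf(path, effect_filter, missing_policy) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no samples")

    columns: dict[str, np.ndarray] = {}
    annotations: dict[str, VariantAnnotation] = {}
    n_missing = 0
    for var in vcf:
        ann_field = var.INFO.get("ANN")
        if ann_field is None:
            continue
        # ANN per alt allele: allele|effect|impact|gene_name|gene_id|...
        per_alt: dict[str, tuple[str, str]] = {}
        for entry in str(ann_field).split(","):
            bits = entry.split("|")
            if len(bits) < 4:
                continue
            allele, effect, gene = bits[0], bits[1], bits[3]
            if not gene and len(bits) > 4:
                gene = bits[4]
            per_alt.setdefault(allele, (effect, gene))
        genotypes = var.genotypes  # [a0, a1, phased] or [a0, phased]
        for k, alt in enumerate(var.ALT):
            if alt not in per_alt:
                continue
            effect, gene = per_alt[alt]
            eclass = classify_effect(effect)
            if eclass not in effect_filter or not gene:
                continue
            vid = var.ID if var.ID not in (None, ".", "") else None
            if vid is None or len(var.ALT) > 1:
                vid = f"{var.CHROM}:{var.POS}:{var.REF}>{alt}"
            col = np.zeros(len(samples), dtype=np.int8)
            has_missing = False
            for i, gt in enumerate(genotypes):
                alleles = [a for a in gt[:-1] if a is not None]
                if any(a < 0 for a in alleles):
                    n_missing += 1
                    has_missing = True
                    continue  # missing -> reference under "ref" policy
                if (k + 1) in alleles:
                    col[i] = 1
            if missing_policy == "drop" and has_missing:
                continue
            columns[vid] = col
            annotations[vid] = VariantAnnotation(
                vid, var.CHROM, var.POS, var.REF, alt, gene, eclass
            )
    if n_missing:
        logger.warning("scored %d missing genotype calls as reference", n_missing)
    if not columns:
        raise ValueError(
            f"{path}: no variants survive the effect filter {sorted(effect_filter)}"
        )
    values = pd.DataFrame(columns, index=pd.Index(samples, name="strain"))
    return GenotypeMatrix(values.astype(np.int8), annotations)


def _read_tsv(path, effect_filter) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"strain_id": str, "variant_id": str})
    required = {"strain_id", "variant_id", "gene", "effect"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    if "value" not in df.columns:
        df["value"] = 1
    df["effect_class"] = df["effect"].map(classify_effect)
    df = df[df["effect_class"].isin(effect_filter)]
    if df.empty:
        raise ValueError(
            f"{path}: no variants survive the effect filter {sorted(effect_filter)}"
        )
    values = (
        df.pivot_table(
            index="strain_id", columns="variant_id", values="value",
            aggfunc="max", fill_value=0,
        )
        .astype(np.int8)
    )
    values.index.name = "strain"
    annotations = {}
    meta = df.drop_duplicates("variant_id").set_index("variant_id")
    for vid, row in meta.iterrows():
        annotations[vid] = VariantAnnotation(
            variant_id=vid,
            chrom=str(row.get("chrom", "syn")),
            pos=int(row.get("pos", 1)),
            ref_allele=str(row.get("ref", "N")),
            alt_allele=str(row.get("alt", "V")),
            gene=str(row["gene"]),
            effect_class=row["effect_class"],
        )
    return GenotypeMatrix(values, annotations)


# ---------------------------------------------------------------------------
# gene collapse


def collapse_to_genes(gm: GenotypeMatrix) -> GeneMutationMatrix:
    """OR-collapse variant columns to genes.

    ``gene_value(s, g) = 1`` iff at least one of gene *g*'s variants is
    present in strain *s*; gene order is lexicographic.
    """
    gene_of = {v: gm.annotations[v].gene for v in gm.variants}
    grouped = gm.values.T.groupby(pd.Series(gene_of)).max().T
    grouped = grouped[sorted(grouped.columns)].astype(np.int8)
    grouped.columns.name = "gene"
    return GeneMutationMatrix(grouped)
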