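"""System-level mutation burden: the ontotype encoding.

The ontotype of a strain is the vector, over all ontology terms, of the
number of that strain's mutated genes falling in each term's propagated gene
set.  Counts are raw integers -- the encoding is deliberately parameter-free.
Genes absent from the ontology contribute to no term; the root's entry equals
the number of mutated genes that appear anywhere in the ontology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .genotype import GeneMutationMatrix
from .ontology import Ontology

__all__ = ["OntotypeMatrix", "compute_ontotype"]


@dataclass
class OntotypeMatrix:
    """Strains x terms matrix of mutated-gene counts, plus term metadata."""

    values: pd.DataFrame  # non-negative integers
    term_meta: pd.DataFrame  # index: term; columns: namespace, n_genes

    @property
    def strains(self) -> list[str]:
        return list(self.values.index)

    @property
    def terms(self) -> list[str]:
        return list(self.values.columns)

    def write(self, matrix_path, meta_path=None) -> None:
        self.values.to_csv(matrix_path, sep="\t")
        if meta_path is not None:
            self.term_meta.to_csv(meta_path, sep="\t")


def compute_ontotype(
    genes: GeneMutationMatrix,
    ont: Ontology,
    normalize: bool = False,
    min_genes: int | None = None,
    max_genes: int | None = None,
) -> OntotypeMatrix:
    """Count mutated genes per (strain, term) over propagated annotations.

    Parameters
    ----------
    genes
        Binary strains x genes mutation matrix.
    ont
        Pruned, rooted ontology.
    normalize
        Divide each term's count by its propagated gene-set size
        (off by default: the encoding is a raw burden count).
    min_genes, max_genes
        Optional term-size filters (off by default; all terms are used).
    """
    prop = ont.propagated_annotations
    matrix_genes = pd.Index(genes.genes)
    shared = set(matrix_genes) & set(ont.genes)
    if not shared:
        raise ValueError(
            "no overlap between gene-matrix IDs and ontology gene IDs; "
            f"matrix sample: {genes.genes[:5]}, "
            f"ontology sample: {sorted(ont.genes)[:5]}"
        )

    terms = sorted(prop)
    if min_genes is not None:
        terms = [t for t in terms if len(prop[t]) >= min_genes]
    if max_genes is not None:
        terms = [t for t in terms if len(prop[t]) <= max_genes]

    gene_pos = {g: i for i, g in enumerate(matrix_genes)}
    rows, cols = [], []
    for j, t in enumerate(terms):
        for g in prop[t]:
            i = gene_pos.get(g)
            if i is not None:
                rows.append(i)
                cols.append(j)
    incidence = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int64), (rows, cols)),
        shape=(len(matrix_genes), len(terms)),
    )
    counts = genes.values.to_numpy(dtype=np.int64) @ incidence.toarray()
    if normalize:
        sizes = np.array([max(len(prop[t]), 1) for t in terms], dtype=float)
        counts = counts / sizes
    values = pd.DataFrame(counts, index=genes.values.index, columns=terms)
    values.columns.name = "term"
    meta = pd.DataFrame(
        {
            "namespace": [ont.namespace.get(t, "data-driven") for t in terms],
            "n_genes": [len(prop[t]) for t in terms],
        },
        index=pd.Index(terms, name="term"),
    )
    return OntotypeMatrix(values, meta)
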