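"""Ontologies as rooted DAGs of gene systems.

A *system* (term) is a node in a directed acyclic graph; genes are annotated
directly to terms and propagate upward so that every term's gene set is the
union of its own annotations and those of all its descendants.  This is the
hierarchy over which mutation burden is counted.

Supported sources:

* OBO 1.2/1.4 structure (``is_a`` plus ``part_of`` relationships; obsolete
  terms dropped) with gene-to-term annotations from GAF 2.x or a two-column
  ``gene<TAB>term`` table;
* a generic three-column edge list ``parent<TAB>child<TAB>type`` where type is
  ``default``/``term`` for term-term containment and ``gene`` for a direct
  gene annotation -- the export dialect of data-driven (CliXO-style)
  hierarchies.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Ontology",
    "load_ontology",
    "prune_ontology",
    "join_under_root",
]

# GO namespaces plus the two synthetic kinds used by this package.
_NAMESPACES = ("BP", "MF", "CC", "data-driven", "artificial")
_NS_FROM_OBO = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}


class Ontology:
    """A DAG of terms with direct and propagated gene annotations.

    Edges point child -> parent.  Gene identifiers are case-sensitive verbatim
    strings; no symbol/ORF harmonisation is attempted.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]],
        direct_annotations: Mapping[str, Iterable[str]],
        namespace: Mapping[str, str] | None = None,
        terms: Iterable[str] | None = None,
    ):
        g = nx.DiGraph()
        if terms is not None:
            g.add_nodes_from(terms)
        for child, parent in edges:
            g.add_edge(child, parent)
        for t in direct_annotations:
            if t not in g:
                g.add_node(t)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"ontology structure is cyclic, e.g. {cycle}")
        self.graph = g
        self.direct_annotations: dict[str, frozenset[str]] = {
            t: frozenset(direct_annotations.get(t, ())) for t in g.nodes
        }
        self.namespace: dict[str, str] = dict(namespace or {})
        for t in g.nodes:
            self.namespace.setdefault(t, "data-driven")
        self._propagated: dict[str, frozenset[str]] | None = None

    # -- structure ---------------------------------------------------------

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        """Child -> parent links."""
        return list(self.graph.edges)

    def children(self, term: str) -> set[str]:
        return set(self.graph.predecessors(term))

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))

    @property
    def roots(self) -> list[str]:
        return sorted(t for t in self.graph.nodes if self.graph.out_degree(t) == 0)

    @property
    def root(self) -> str:
        roots = self.roots
        if len(roots) != 1:
            raise ValueError(f"ontology has {len(roots)} roots: {roots[:5]}")
        return roots[0]

    @property
    def genes(self) -> frozenset[str]:
        """All genes annotated anywhere in the ontology."""
        out: set[str] = set()
        for s in self.direct_annotations.values():
            out |= s
        return frozenset(out)

    # -- propagation -------------------------------------------------------

    @property
    def propagated_annotations(self) -> dict[str, frozenset[str]]:
        """Term -> union of its own genes and those of all descendants."""
        if self._propagated is None:
            prop: dict[str, set[str]] = {}
            # children precede parents in topological order of child->parent edges
            for t in nx.topological_sort(self.graph):
                s = set(self.direct_annotations.get(t, ()))
                for c in self.graph.predecessors(t):
                    s |= prop[c]
                prop[t] = s
            self._propagated = {t: frozenset(s) for t, s in prop.items()}
        return self._propagated

    def term_sizes(self) -> pd.Series:
        return pd.Series(
            {t: len(s) for t, s in self.propagated_annotations.items()}, name="n_genes"
        ).sort_index()

    # -- I/O ---------------------------------------------------------------

    def to_edgelist(self) -> pd.DataFrame:
        """Three-column (parent, child, type) frame, genes as ``gene`` rows."""
        rows = [(p, c, "default") for c, p in sorted(self.graph.edges)]
        for t in sorted(self.direct_annotations):
            for g in sorted(self.direct_annotations[t]):
                rows.append((t, g, "gene"))
        return pd.DataFrame(rows, columns=["parent", "child", "type"])

    def write_edgelist(self, path) -> None:
        self.to_edgelist().to_csv(path, sep="\t", index=False, header=False)

    def copy(self) -> "Ontology":
        return Ontology(
            self.edges,
            {t: set(s) for t, s in self.direct_annotations.items()},
            dict(self.namespace),
            terms=self.graph.nodes,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<Ontology: {self.graph.number_of_nodes()} terms, "
            f"{self.graph.number_of_edges()} edges, {len(self.genes)} genes>"
        )


# ---------------------------------------------------------------------------
# loading


def _read_obo_structure(path):
    import obonet

    g = obonet.read_obo(path)  # obsolete terms are skipped by default
    edges = []
    namespace = {}
    for node, data in g.nodes(data=True):
        ns = _NS_FROM_OBO.get(data.get("namespace", ""), "data-driven")
        namespace[node] = ns
    for child, parent, key in g.edges(keys=True):
        if key in ("is_a", "part_of"):
            edges.append((child, parent))
    return list(g.nodes), edges, namespace


def _read_gaf(path) -> list[tuple[str, str]]:
    """(gene, term) pairs from a GAF 2.x file; qualifier NOT rows skipped."""
    from Bio.UniProt.GOA import gafiterator

    pairs = []
    with open(path) as fh:
        for rec in gafiterator(fh):
            if any(q.startswith("NOT") for q in rec.get("Qualifier", [])):
                continue
            pairs.append((rec["DB_Object_ID"], rec["GO_ID"]))
    return pairs


def _read_two_column(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns (gene, term)")
    return list(df.iloc[:, :2].itertuples(index=False, name=None))


def _read_edgelist(path):
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise ValueError(
            f"{path}: expected three tab-separated columns (parent, child, type)"
        )
    df.columns = ["parent", "child", "type"] + list(df.columns[3:])
    term_edges = []
    annotations: dict[str, set[str]] = {}
    terms: set[str] = set()
    for parent, child, kind in df[["parent", "child", "type"]].itertuples(
        index=False, name=None
    ):
        kind = (kind or "default").strip().lower()
        if kind == "gene":
            annotations.setdefault(parent, set()).add(child)
            terms.add(parent)
        elif kind in ("default", "term"):
            term_edges.append((child, parent))  # file stores parent first
            terms.update((parent, child))
        else:
            raise ValueError(f"unknown edge type {kind!r} in {path}")
    return terms, term_edges, annotations


def _looks_like_obo(path) -> bool:
    p = str(path)
    if p.endswith(".obo"):
        return True
    try:
        with open(path) as fh:
            head = fh.read(4096)
    except OSError:
        return False
    return "[Term]" in head or head.startswith("format-version")


def load_ontology(
    structure_source,
    annotation_source=None,
    namespace: str | None = None,
) -> Ontology:
    """Load an ontology from OBO or a generic edge list.

    Parameters
    ----------
    structure_source
        OBO file, or a three-column (parent, child, type) edge list.  Edge
        lists may embed gene annotations as ``gene`` rows.
    annotation_source
        GAF 2.x file or two-column ``gene<TAB>term`` table.  Required for OBO
        input unless the edge list embeds gene rows.
    namespace
        Override namespace label for every term (edge-list input only).
    """
    structure_source = Path(structure_source)
    if _looks_like_obo(structure_source):
        terms, edges, ns = _read_obo_structure(structure_source)
        annotations: dict[str, set[str]] = {}
    else:
        terms, edges, annotations = _read_edgelist(structure_source)
        ns = {t: namespace or "data-driven" for t in terms}

    if annotation_source is not None:
        p = str(annotation_source)
        if p.endswith(".gaf") or _is_gaf(annotation_source):
            pairs = _read_gaf(annotation_source)
        else:
            pairs = _read_two_column(annotation_source)
        term_set = set(terms)
        skipped = 0
        for gene, term in pairs:
            if not gene:
                continue
            if term not in term_set:
                skipped += 1
                continue
            annotations.setdefault(term, set()).add(gene)
        if skipped:
            warnings.warn(
                f"{skipped} annotation rows referenced unknown terms and were skipped"
            )
            logger.info("skipped %d annotations to unknown terms", skipped)

    if not any(annotations.values()):
        raise ValueError("ontology has an empty annotation set: no gene is annotated")

    ont = Ontology(edges, annotations, ns, terms=terms)
    ont.propagated_annotations  # force computation + cycle check already done
    return ont


def _is_gaf(path) -> bool:
    try:
        with open(path) as fh:
            return fh.readline().startswith("!gaf")
    except OSError:
        return False


# ---------------------------------------------------------------------------
# pruning and rooting


def prune_ontology(ont: Ontology) -> Ontology:
    """Drop uninformative terms.

    A term is removed when (1) no gene propagates to it, or (2) its propagated
    gene set is identical to that of at least one child -- the parent carries
    no information beyond the more specific term.  Parents of a removed term
    are rewired to its children, so gene content above the removal point is
    unchanged; the root is never removed.
    """
    prop = ont.propagated_annotations
    g = ont.graph.copy()
    roots = set(ont.roots)
    removed = 0
    # children first, so a node's surviving children are final when visited
    for t in list(nx.topological_sort(ont.graph)):
        if t in roots:
            if not prop[t]:
                logger.warning("root %s has no propagated genes; kept regardless", t)
            continue
        drop = not prop[t] or any(prop[c] == prop[t] for c in g.predecessors(t))
        if drop:
            parents = list(g.successors(t))
            kids = list(g.predecessors(t))
            g.remove_node(t)
            for p in parents:
                for c in kids:
                    g.add_edge(c, p)
            removed += 1
    logger.info("pruning removed %d of %d terms", removed, len(prop))
    keep = set(g.nodes)
    return Ontology(
        g.edges,
        {t: set(s) for t, s in ont.direct_annotations.items() if t in keep},
        {t: ns for t, ns in ont.namespace.items() if t in keep},
        terms=keep,
    )


def join_under_root(onts, root_id: str = "ROOT") -> Ontology:
    """Join one or more ontologies (or a multi-rooted one) under a single root.

    An artificial root is added with one edge per former root.  If the input
    is a single ontology already rooted at ``root_id``, it is returned
    unchanged (as a copy).
    """
    if isinstance(onts, Ontology):
        onts = [onts]
    if not onts:
        raise ValueError("need at least one ontology")

    edges: list[tuple[str, str]] = []
    annotations: dict[str, set[str]] = {}
    namespace: dict[str, str] = {}
    terms: set[str] = set()
    old_roots: list[str] = []
    for ont in onts:
        if terms & ont.terms:
            raise ValueError(f"duplicate terms across ontologies: "
                             f"{sorted(terms & ont.terms)[:5]}")
        terms |= ont.terms
        edges += ont.edges
        for t, s in ont.direct_annotations.items():
            annotations.setdefault(t, set()).update(s)
        namespace.update(ont.namespace)
        old_roots += ont.roots

    if old_roots == [root_id]:
        return onts[0].copy()
    if root_id in terms:
        raise ValueError(f"root id {root_id!r} collides with an existing term")
    for r in old_roots:
        edges.append((r, root_id))
    namespace[root_id] = "artificial"
    terms.add(root_id)
    return Ontology(edges, annotations, namespace, terms=terms)
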