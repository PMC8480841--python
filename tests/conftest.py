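"""Shared fixtures: random DAG ontologies, an independent propagation oracle,
and small VCF/OBO/GAF text fixtures written at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ontogwas.ontology import Ontology


def make_random_dag(rng: np.random.Generator, n_terms: int = 50,
                    n_genes: int = 100, extra_edge_p: float = 0.3,
                    annotate_internal: bool = True) -> Ontology:
    """Random single-rooted DAG with genes annotated to random terms."""
    terms = [f"T{i:03d}" for i in range(n_terms)]
    edges = []
    for i in range(1, n_terms):
        parent = terms[rng.integers(0, i)]
        edges.append((terms[i], parent))
        if i > 1 and rng.random() < extra_edge_p:
            other = terms[rng.integers(0, i)]
            if other != parent:
                edges.append((terms[i], other))
    genes = [f"g{j:03d}" for j in range(n_genes)]
    annotations: dict[str, set] = {}
    lo = 1 if annotate_internal else max(1, n_terms // 2)
    for g in genes:
        t = terms[rng.integers(lo, n_terms)] if n_terms > 1 else terms[0]
        annotations.setdefault(t, set()).add(g)
    return Ontology(edges, annotations)


def brute_force_propagated(ont: Ontology) -> dict[str, set]:
    """Oracle: per-term union of direct annotations over all DAG descendants,
    found by breadth-first enumeration over the raw edge list."""
    children: dict[str, list] = {}
    for child, parent in ont.edges:
        children.setdefault(parent, []).append(child)
    out = {}
    for t in ont.terms:
        seen = {t}
        frontier = [t]
        while frontier:
            node = frontier.pop()
            for c in children.get(node, []):
                if c not in seen:
                    seen.add(c)
                    frontier.append(c)
        s: set = set()
        for node in seen:
            s |= set(ont.direct_annotations.get(node, ()))
        out[t] = s
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(0)


OBO_TEXT = """\
format-version: 1.2

[Term]
id: GO:0000001
name: bp root
namespace: biological_process

[Term]
id: GO:0000002
name: child a
namespace: biological_process
is_a: GO:0000001 ! bp root

[Term]
id: GO:0000003
name: part child
namespace: biological_process
relationship: part_of GO:0000001 ! bp root

[Term]
id: GO:0000009
name: gone
namespace: biological_process
is_a: GO:0000001 ! bp root
is_obsolete: true

[Term]
id: GO:0000004
name: mf root
namespace: molecular_function
"""

GAF_TEXT = """\
!gaf-version: 2.1
SGD\tg1\tG1\t\tGO:0000002\tPMID:1\tIEA\t\tP\tdesc\tg1\tgene\ttaxon:4932\t20210101\tSGD\t\t
SGD\tg2\tG2\t\tGO:0000003\tPMID:1\tIEA\t\tP\tdesc\tg2\tgene\ttaxon:4932\t20210101\tSGD\t\t
SGD\tg3\tG3\tNOT\tGO:0000002\tPMID:1\tIEA\t\tP\tdesc\tg3\tgene\ttaxon:4932\t20210101\tSGD\t\t
SGD\tg4\tG4\t\tGO:0000004\tPMID:1\tIEA\t\tF\tdesc\tg4\tgene\ttaxon:4932\t20210101\tSGD\t\t
SGD\tg5\tG5\t\tGO:9999999\tPMID:1\tIEA\t\tP\tdesc\tg5\tgene\ttaxon:4932\t20210101\tSGD\t\t
"""

VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=chrI,length=230218>
##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
chrI\t100\t.\tA\tG\t.\t.\tANN=G|missense_variant|MODERATE|GENE1|Y001|t|c|p|1/2|n|p|1|1|1\tGT\t0/0\t1/1\t0/1
chrI\t200\trs2\tC\tT\t.\t.\tANN=T|missense_variant|MODERATE|GENE2|Y002|t|c|p|1/2|n|p|1|1|1\tGT\t0/0\t0/0\t./.
chrI\t300\t.\tG\tA\t.\t.\tANN=A|stop_gained|HIGH|GENE2|Y002|t|c|p|1/2|n|p|1|1|1\tGT\t1/1\t0/0\t0/0
chrI\t400\t.\tT\tC\t.\t.\tANN=C|synonymous_variant|LOW|GENE3|Y003|t|c|p|1/2|n|p|1|1|1\tGT\t0/1\t0/1\t0/0
chrI\t500\t.\tA\tT\t.\t.\tANN=T|intergenic_region|MODIFIER|||t|c|p|1/2|n|p|1|1|1\tGT\t0/0\t0/1\t0/0
chrI\t600\t.\tG\tA,C\t.\t.\tANN=A|missense_variant|MODERATE|GENE4|Y004|t|c|p|1/2|n|p|1|1|1,C|missense_variant|MODERATE|GENE4|Y004|t|c|p|1/2|n|p|1|1|1\tGT\t1/2\t0/2\t0/0
"""


@pytest.fixture
def obo_files(tmp_path):
    obo = tmp_path / "mini.obo"
    gaf = tmp_path / "mini.gaf"
    obo.write_text(OBO_TEXT)
    gaf.write_text(GAF_TEXT)
    return obo, gaf


@pytest.fixture
def vcf_file(tmp_path):
    path = tmp_path / "mini.vcf"
    path.write_text(VCF_TEXT)
    return path


@pytest.fixture
def small_study():
    """A small simulated study shared by a few integration-flavoured tests."""
    from ontogwas import SimulationConfig, simulate_study

    return simulate_study(SimulationConfig(
        n_strains=150, n_snvs=500, n_genes=150, ontology_shape=(40, 3, 3),
        planted_systems=[(None, 1.0, -1)], target_h2=0.5,
        structure_effect=0.1, seed=11))
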