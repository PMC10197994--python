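"""GO term enrichment: hypergeometric tests with an elim-style hierarchy
correction.

Annotations are first closed under the true-path rule (a gene annotated to
a term is annotated to every ancestor).  Terms are then tested
leaves-to-root; when a term is significant at ``alpha`` its genes are
removed from all of its ancestors before those are tested, so broad parent
terms are not dragged along by a specific child's signal — the "elim"
algorithm.  Both the uncorrected (classic Fisher) and elim p-values are
reported; following the convention of hierarchy-aware enrichment tools,
no further multiple-testing correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
from scipy.stats import hypergeom

NAMESPACES = ("BP", "MF", "CC")


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    namespace: str
    study_count: int
    population_count: int
    study_size: int
    population_size: int
    p_raw: float
    p_elim: float


def hypergeometric_test(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    k = study genes carrying the term, n = study size, K = population genes
    carrying the term, N = population size.
    """
    if not (0 <= k <= min(n, K) <= N and n <= N and k >= max(0, n + K - N)):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def load_ontology(path: str | Path) -> nx.DiGraph:
    """Read (child, parent, namespace) TSV rows into a child->parent DAG."""
    dag = nx.DiGraph()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            child, parent, ns = line.split("\t")
            dag.add_edge(child, parent)
            dag.nodes[child].setdefault("namespace", ns)
            dag.nodes[parent].setdefault("namespace", ns)
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError(f"{path}: ontology relations contain a cycle")
    return dag


def load_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read gene -> term TSV rows."""
    ann: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            ann.setdefault(gene, set()).add(term)
    return ann


def annotate_up_propagate(
    annotations: dict[str, set[str]], dag: nx.DiGraph
) -> dict[str, set[str]]:
    """Close each gene's term set under ancestors (true-path rule).

    Terms absent from the ontology are skipped with a warning.
    """
    ancestors: dict[str, set[str]] = {}
    out: dict[str, set[str]] = {}
    for gene, terms in annotations.items():
        closed: set[str] = set()
        for t in terms:
            if t not in dag:
                warnings.warn(f"unknown ontology term {t!r} skipped")
                continue
            if t not in ancestors:
                # ancestors = nodes reachable along child->parent edges
                ancestors[t] = nx.descendants(dag, t)
            closed.add(t)
            closed |= ancestors[t]
        out[gene] = closed
    return out


def elim_enrichment(
    study: set[str],
    population: set[str],
    annotations: dict[str, set[str]],
    dag: nx.DiGraph,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment over all annotated terms with elim.

    ``annotations`` are direct gene->term assignments; up-propagation is
    applied here.  The background gene universe (``population``) is an
    explicit, required choice.  Terms are processed children-before-parents
    (topological order of the child->parent DAG); a term significant at
    ``alpha`` has its genes removed from all ancestor terms before they are
    tested.
    """
    if not study <= population:
        raise ValueError("study set must be a subset of the population")
    closed = annotate_up_propagate(annotations, dag)
    genes_of: dict[str, set[str]] = {}
    for gene in population:
        for t in closed.get(gene, ()):
            genes_of.setdefault(t, set()).add(gene)

    N = len(population)
    n = len(study)
    removed: dict[str, set[str]] = {t: set() for t in genes_of}
    results: dict[str, EnrichmentResult] = {}
    order = [t for t in nx.topological_sort(dag) if t in genes_of]
    for term in order:
        ann_genes = genes_of[term]
        p_raw = hypergeometric_test(
            len(ann_genes & study), n, len(ann_genes), N
        )
        kept = ann_genes - removed[term]
        p_elim = hypergeometric_test(len(kept & study), n, len(kept), N)
        ns = dag.nodes[term].get("namespace", "BP")
        results[term] = EnrichmentResult(
            term, ns, len(kept & study), len(kept), n, N, p_raw, p_elim
        )
        if p_elim < alpha:
            for anc in nx.descendants(dag, term):
                if anc in removed:
                    removed[anc] |= ann_genes
    return sorted(results.values(), key=lambda r: (r.p_elim, r.term))


def write_results_tsv(results: list[EnrichmentResult], path: str | Path) -> None:
    import math

    with open(path, "w") as fh:
        fh.write(
            "term\tnamespace\tstudy_count\tpopulation_count\tstudy_size\t"
            "population_size\tp_raw\tp_elim\tneg_log10_p_elim\n"
        )
        for r in results:
            fh.write(
                f"{r.term}\t{r.namespace}\t{r.study_count}\t{r.population_count}"
                f"\t{r.study_size}\t{r.population_size}\t{r.p_raw:.6g}\t"
                f"{r.p_elim:.6g}\t{-math.log10(r.p_elim):.4f}\n"
            )
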