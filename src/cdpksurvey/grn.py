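"""Reciprocal-best-hit homology mapping and interolog network projection.

Target and reference proteomes are searched against each other with the
same local aligner and e-value proxy used for family identification; a
homolog pair exists when two proteins are each other's single best hit at
e <= 1e-5.  Reference network edges are transferred to the target species
whenever both endpoints have homolog pairs, and family-centred subnetworks
are the seed genes plus their bounded-hop neighborhoods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .core_io import ProteinSequence
from .identify import align_score, evalue_proxy


@dataclass(frozen=True)
class HomologPair:
    target_id: str
    reference_id: str
    forward_score: float
    reverse_score: float


def score_matrix(
    proteome_a: list[ProteinSequence], proteome_b: list[ProteinSequence]
) -> np.ndarray:
    """Local alignment scores for every A x B pair (symmetric scoring, so
    one matrix serves both search directions)."""
    m = np.zeros((len(proteome_a), len(proteome_b)))
    for i, a in enumerate(proteome_a):
        for j, b in enumerate(proteome_b):
            m[i, j] = align_score(a, b)
    return m


def _best_hits_from_matrix(
    proteome_a: list[ProteinSequence],
    proteome_b: list[ProteinSequence],
    scores: np.ndarray,
    evalue_cutoff: float,
) -> dict[str, tuple[str, float]]:
    out: dict[str, tuple[str, float]] = {}
    for i, a in enumerate(proteome_a):
        best_j, best_score = None, -np.inf
        for j, b in enumerate(proteome_b):
            s = scores[i, j]
            if evalue_proxy(s, a.length, b.length) > evalue_cutoff:
                continue
            if s == best_score:
                warnings.warn(
                    f"{a.seq_id}: best-hit tie broken lexicographically"
                )
                if b.seq_id < proteome_b[best_j].seq_id:
                    best_j = j
            elif s > best_score:
                best_j, best_score = j, s
        if best_j is not None:
            out[a.seq_id] = (proteome_b[best_j].seq_id, float(best_score))
    return out


def best_hit_map(
    proteome_a: list[ProteinSequence],
    proteome_b: list[ProteinSequence],
    evalue_cutoff: float = 1e-5,
) -> dict[str, str]:
    """Single highest-scoring qualifying B protein per A protein."""
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")
    scores = score_matrix(proteome_a, proteome_b)
    hits = _best_hits_from_matrix(proteome_a, proteome_b, scores, evalue_cutoff)
    return {a: b for a, (b, _) in hits.items()}


def reciprocal_pairs(
    map_ab: dict[str, str], map_ba: dict[str, str],
    scores_ab: dict[str, float] | None = None,
    scores_ba: dict[str, float] | None = None,
) -> list[HomologPair]:
    """Pairs (a, b) with map_ab[a] == b and map_ba[b] == a."""
    out = []
    for a, b in sorted(map_ab.items()):
        if map_ba.get(b) == a:
            out.append(
                HomologPair(
                    a, b,
                    (scores_ab or {}).get(a, 0.0),
                    (scores_ba or {}).get(b, 0.0),
                )
            )
    return out


def reciprocal_best_hits(
    target_proteome: list[ProteinSequence],
    reference_proteome: list[ProteinSequence],
    evalue_cutoff: float = 1e-5,
    strict: bool = True,
) -> list[HomologPair]:
    """RBH pairs computed from one score matrix (scores are symmetric).

    ``strict=False`` relaxes reciprocity to one-way best hits (the target's
    best reference), still at the e-value cutoff.
    """
    if not target_proteome or not reference_proteome:
        raise ValueError("both proteomes must be non-empty")
    scores = score_matrix(target_proteome, reference_proteome)
    fwd = _best_hits_from_matrix(
        target_proteome, reference_proteome, scores, evalue_cutoff
    )
    rev = _best_hits_from_matrix(
        reference_proteome, target_proteome, scores.T, evalue_cutoff
    )
    if not strict:
        return [
            HomologPair(a, b, s, rev.get(b, (None, 0.0))[1])
            for a, (b, s) in sorted(fwd.items())
        ]
    return reciprocal_pairs(
        {a: b for a, (b, _) in fwd.items()},
        {b: a for b, (a, _) in rev.items()},
        {a: s for a, (_, s) in fwd.items()},
        {b: s for b, (_, s) in rev.items()},
    )


# ---------------------------------------------------------------------------
# projection


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b, *_ = line.split("\t")
            edges.append((a, b))
    return edges


def project_network(
    reference_edges: list[tuple[str, str]],
    pairs: list[HomologPair],
    family_ids: set[str] | None = None,
) -> nx.Graph:
    """Transfer reference edges onto target genes through homolog pairs.

    An edge (t1, t2) appears iff a reference edge (r1, r2) exists with
    t1<->r1 and t2<->r2; self-loops are dropped and duplicates merged.
    """
    to_target: dict[str, str] = {}
    seen_t, seen_r = set(), set()
    for p in pairs:
        if p.target_id in seen_t or p.reference_id in seen_r:
            raise ValueError("homolog pairs must be unique per id")
        seen_t.add(p.target_id)
        seen_r.add(p.reference_id)
        to_target[p.reference_id] = p.target_id
    g = nx.Graph()
    for r1, r2 in reference_edges:
        t1, t2 = to_target.get(r1), to_target.get(r2)
        if t1 is None or t2 is None or t1 == t2:
            continue
        g.add_edge(t1, t2)
    for node in g.nodes:
        g.nodes[node]["is_family_member"] = bool(
            family_ids and node in family_ids
        )
    return g


def extract_subnetwork(
    net: nx.Graph, seed_ids: list[str], hops: int = 1
) -> tuple[nx.Graph, dict[str, int]]:
    """Induced subgraph on the seeds and their <=hops neighborhoods, plus
    each seed's number of distinct interactors in the full network."""
    present = [s for s in seed_ids if s in net]
    missing = sorted(set(seed_ids) - set(present))
    if missing:
        warnings.warn(f"seed genes absent from the network: {missing}")
    keep: set[str] = set(present)
    frontier = set(present)
    for _ in range(hops):
        frontier = {
            n for f in frontier for n in net.neighbors(f)
        } - keep
        keep |= frontier
    sub = net.subgraph(keep).copy()
    degrees = {s: net.degree(s) for s in present}
    return sub, degrees


def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"{a}\t{b}\n")


def write_interchange_graph(g: nx.Graph, path: str | Path) -> None:
    """Simple node/edge interchange format for viewer import (GML)."""
    sg = nx.Graph()
    sg.add_nodes_from(sorted(g.nodes(data=True)))
    sg.add_edges_from(sorted(tuple(sorted(e)) for e in g.edges))
    nx.write_gml(sg, str(path))
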