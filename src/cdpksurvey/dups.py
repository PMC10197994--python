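"""Duplicate-gene detection and tandem/segmental classification.

A pair of family genes is a duplication when the local alignment covers
more than 80% of the longer protein at more than 80% identity.  Tightly
linked same-chromosome copies (at most ``max_intervening`` genes between
them, or within ``max_distance_bp``) collapse into one cluster that counts
as a single tandem event; every other collapsed pair is a segmental event.
Collinearity-block synteny is deliberately not modelled: segmental means
"duplicated but not tandem".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .core_io import GeneRecord, ProteinSequence
from .identify import AlignmentResult, local_align

TANDEM = "tandem"
SEGMENTAL = "segmental"

MAX_TANDEM_DISTANCE_BP = 100_000


@dataclass(frozen=True)
class DuplicationEvent:
    gene_a: str
    gene_b: str
    identity: float
    coverage_of_longer: float
    kind: str
    cluster_id: str

    def __post_init__(self) -> None:
        if not (self.identity > 0.8 and self.coverage_of_longer > 0.8):
            raise ValueError(
                f"{self.gene_a}/{self.gene_b}: duplication thresholds violated"
            )
        if self.kind not in (TANDEM, SEGMENTAL):
            raise ValueError(f"unknown duplication kind {self.kind!r}")


def find_duplicate_pairs(
    member_ids: list[str],
    proteins: dict[str, ProteinSequence],
    min_identity: float = 0.8,
    min_coverage: float = 0.8,
) -> list[tuple[str, str, AlignmentResult]]:
    """All unordered member pairs passing both strict >80% rules."""
    missing = [m for m in member_ids if m not in proteins]
    if missing:
        raise ValueError(f"members without sequences: {missing}")
    out = []
    for a, b in itertools.combinations(sorted(member_ids), 2):
        res = local_align(proteins[a], proteins[b])
        if res.identity > min_identity and res.coverage > min_coverage:
            out.append((a, b, res))
    return out


def _gene_ranks(gene_records: dict[str, GeneRecord]) -> dict[str, int]:
    """Rank of every gene in coordinate order along its chromosome."""
    by_chrom: dict[str, list[GeneRecord]] = {}
    for rec in gene_records.values():
        by_chrom.setdefault(rec.chromosome, []).append(rec)
    ranks = {}
    for recs in by_chrom.values():
        recs.sort(key=lambda r: (r.start, r.end))
        for i, rec in enumerate(recs):
            ranks[rec.gene_id] = i
    return ranks


def _is_tight(
    a: GeneRecord, b: GeneRecord, ranks: dict[str, int],
    max_intervening: int, max_distance_bp: int,
) -> bool:
    if a.chromosome != b.chromosome:
        return False
    intervening = abs(ranks[a.gene_id] - ranks[b.gene_id]) - 1
    close = abs(a.midpoint - b.midpoint) <= max_distance_bp
    return intervening <= max_intervening or close


def collapse_tight_clusters(
    pairs: list[tuple[str, str, AlignmentResult]],
    gene_records: dict[str, GeneRecord],
    max_intervening: int = 1,
    max_distance_bp: int = MAX_TANDEM_DISTANCE_BP,
) -> tuple[list[list[str]], dict[str, str]]:
    """Merge tightly linked duplicated genes into clusters.

    Returns (clusters, gene -> cluster id).  Singleton "clusters" are the
    duplicated genes that are not tightly linked to any partner.
    """
    ranks = _gene_ranks(gene_records)
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    genes = sorted({g for a, b, _ in pairs for g in (a, b)})
    for g in genes:
        parent[g] = g
    for a, b, _ in pairs:
        if _is_tight(
            gene_records[a], gene_records[b], ranks, max_intervening,
            max_distance_bp,
        ):
            parent[find(a)] = find(b)
    groups: dict[str, list[str]] = {}
    for g in genes:
        groups.setdefault(find(g), []).append(g)
    clusters = sorted(sorted(v) for v in groups.values())
    cluster_of = {
        g: f"C{idx + 1:02d}" for idx, cl in enumerate(clusters) for g in cl
    }
    return clusters, cluster_of


def classify_events(
    pairs: list[tuple[str, str, AlignmentResult]],
    gene_records: dict[str, GeneRecord],
    max_intervening: int = 1,
    max_distance_bp: int = MAX_TANDEM_DISTANCE_BP,
) -> list[DuplicationEvent]:
    """Collapse tight clusters and classify one event per cluster pair.

    Each multi-gene tight cluster yields one tandem event; each pair of
    distinct clusters with at least one passing alignment between them
    yields one event, classified from the best such pair's gene records:
    tandem when on one chromosome within the tight window, else segmental.
    """
    clusters, cluster_of = collapse_tight_clusters(
        pairs, gene_records, max_intervening, max_distance_bp
    )
    ranks = _gene_ranks(gene_records)
    events: list[DuplicationEvent] = []
    for cl in clusters:
        if len(cl) < 2:
            continue
        best = max(
            (p for p in pairs if cluster_of[p[0]] == cluster_of[cl[0]]
             and cluster_of[p[1]] == cluster_of[cl[0]]),
            key=lambda p: p[2].identity,
        )
        a, b, res = best
        events.append(
            DuplicationEvent(a, b, res.identity, res.coverage, TANDEM,
                             cluster_of[cl[0]])
        )
    # events between distinct clusters: keep the best pair per cluster pair
    between: dict[tuple[str, str], tuple[str, str, AlignmentResult]] = {}
    for a, b, res in pairs:
        ca, cb = cluster_of[a], cluster_of[b]
        if ca == cb:
            continue
        key = (ca, cb) if ca < cb else (cb, ca)
        if key not in between or res.identity > between[key][2].identity:
            between[key] = (a, b, res)
    for key in sorted(between):
        a, b, res = between[key]
        tight = _is_tight(
            gene_records[a], gene_records[b], ranks, max_intervening,
            max_distance_bp,
        )
        kind = TANDEM if tight else SEGMENTAL
        events.append(
            DuplicationEvent(a, b, res.identity, res.coverage, kind,
                             "-".join(key))
        )
    return events


def duplicated_gene_count(pairs: list[tuple[str, str, AlignmentResult]]) -> int:
    """Number of distinct genes involved in any duplication pair."""
    return len({g for a, b, _ in pairs for g in (a, b)})


def write_events_tsv(events: list[DuplicationEvent], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tidentity\tcoverage_of_longer\tkind\tcluster_id\n")
        for e in events:
            fh.write(
                f"{e.gene_a}\t{e.gene_b}\t{e.identity:.4f}\t"
                f"{e.coverage_of_longer:.4f}\t{e.kind}\t{e.cluster_id}\n"
            )


def write_link_file(
    events: list[DuplicationEvent], gene_records: dict[str, GeneRecord], path
) -> None:
    """Per-event chromosome spans of both partners (circular-plot input)."""
    with open(path, "w") as fh:
        for e in events:
            a, b = gene_records[e.gene_a], gene_records[e.gene_b]
            fh.write(
                f"{a.chromosome}\t{a.start}\t{a.end}\t"
                f"{b.chromosome}\t{b.start}\t{b.end}\n"
            )
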