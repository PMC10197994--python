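"""Fallback progressive multiple aligner.

The survey normally consumes a pre-computed alignment (MUSCLE or similar);
this module provides a deterministic stand-in adequate for the synthetic
sequence sets: a guide tree from k-mer distances (average-linkage) drives
progressive profile merges, where each merge globally aligns the two
profiles' consensus sequences (Needleman-Wunsch, BLOSUM62, affine gaps)
and the resulting gap pattern is applied to every row of each profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage

from .core_io import ProteinSequence
from .identify import _make_aligner

GAP = "-"


@dataclass
class MultipleAlignment:
    """Equal-length aligned rows over residues plus gap."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")


def _kmer_distance(seqs: list[str], k: int = 3) -> np.ndarray:
    """1 - Jaccard similarity of k-mer sets, condensed over all pairs."""
    sets = [frozenset(s[i : i + k] for i in range(len(s) - k + 1)) for s in seqs]
    n = len(seqs)
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            union = len(sets[i] | sets[j])
            out.append(1.0 - (len(sets[i] & sets[j]) / union if union else 0.0))
    return np.array(out)


def _consensus(rows: list[str]) -> str:
    cols = zip(*rows)
    out = []
    for col in cols:
        residues = [c for c in col if c != GAP]
        if not residues:
            out.append("X")
            continue
        counts: dict[str, int] = {}
        for c in residues:
            counts[c] = counts.get(c, 0) + 1
        out.append(max(sorted(counts), key=counts.get))
    return "".join(out)


def _merge(a: MultipleAlignment, b: MultipleAlignment,
           aligner) -> MultipleAlignment:
    ca, cb = _consensus(a.rows), _consensus(b.rows)
    aln = aligner.align(ca, cb)[0]
    blocks_a, blocks_b = aln.aligned
    # walk the two block lists emitting merged columns
    cols_a: list[int | None] = []
    cols_b: list[int | None] = []
    pa = pb = 0
    for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
        while pa < sa:
            cols_a.append(pa); cols_b.append(None); pa += 1
        while pb < sb:
            cols_a.append(None); cols_b.append(pb); pb += 1
        while pa < ea:
            cols_a.append(pa); cols_b.append(pb); pa += 1; pb += 1
    while pa < len(ca):
        cols_a.append(pa); cols_b.append(None); pa += 1
    while pb < len(cb):
        cols_a.append(None); cols_b.append(pb); pb += 1

    def expand(rows, cols):
        return [
            "".join(r[c] if c is not None else GAP for c in cols) for r in rows
        ]

    return MultipleAlignment(
        a.ids + b.ids, expand(a.rows, cols_a) + expand(b.rows, cols_b)
    )


def progressive_align(seqs: list[ProteinSequence]) -> MultipleAlignment:
    """Guide-tree-ordered progressive alignment of a sequence set."""
    if not seqs:
        raise ValueError("no sequences to align")
    if len(seqs) == 1:
        return MultipleAlignment([seqs[0].seq_id], [seqs[0].residues])
    aligner = _make_aligner(mode="global")
    profiles: dict[int, MultipleAlignment] = {
        i: MultipleAlignment([s.seq_id], [s.residues]) for i, s in enumerate(seqs)
    }
    if len(seqs) == 2:
        return _merge(profiles[0], profiles[1], aligner)
    z = linkage(_kmer_distance([s.residues for s in seqs]), method="average")
    n = len(seqs)
    for step, (i, j, _, _) in enumerate(z):
        merged = _merge(profiles.pop(int(i)), profiles.pop(int(j)), aligner)
        profiles[n + step] = merged
    (result,) = profiles.values()
    return result


def read_aligned_fasta(path) -> MultipleAlignment:
    from Bio import SeqIO

    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    return MultipleAlignment(ids, rows)


def write_aligned_fasta(aln: MultipleAlignment, path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(aln.ids, aln.rows):
            fh.write(f">{sid}\n{row}\n")
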