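"""Neighbor-joining phylogeny with bootstrap supports and clade-based
assignment of target members to reference groups.

The tree is the classic Saitou-Nei agglomeration on uncorrected p-distances
(pairwise deletion of gap positions).  It is unrooted; the in-memory
representation roots it arbitrarily at a trifurcation, which is also how it
is serialised to Newick.  Bootstrap supports are plain nonparametric column
resamples: the percentage of replicate trees containing each internal
bipartition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import UNGROUPED
from .msa import GAP, MultipleAlignment


@dataclass
class PhyloNode:
    name: str | None = None
    children: list["PhyloNode"] = field(default_factory=list)
    branch_length: float = 0.0
    support: float | None = None  # bootstrap %, internal edges only

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["PhyloNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class PhyloTree:
    """Unrooted tree held as a rooted structure with a trifurcating root."""

    root: PhyloNode

    def leaf_names(self) -> frozenset[str]:
        return self.root.leaf_names()

    def bipartitions(self) -> dict[frozenset[str], PhyloNode]:
        """Non-trivial splits, keyed canonically (side not containing the
        lexicographically first leaf)."""
        all_leaves = self.leaf_names()
        anchor = min(all_leaves)
        out = {}
        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            side = node.leaf_names()
            if anchor in side:
                side = all_leaves - side
            if 1 < len(side) < len(all_leaves) - 1:
                out[side] = node
        return out

    def to_newick(self) -> str:
        def fmt(node: PhyloNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.branch_length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else f"{node.support:g}"
            return f"({inner}){label}:{node.branch_length:.6f}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")


# ---------------------------------------------------------------------------
# distances


def p_distance_matrix(aln: MultipleAlignment) -> np.ndarray:
    """Uncorrected p-distances with pairwise deletion of gap positions."""
    if len(aln.ids) < 3:
        raise ValueError("need at least three sequences")
    chars = np.array([list(r) for r in aln.rows])
    valid = chars != GAP
    n = len(aln.ids)
    d = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        comp = both.sum(axis=1)
        if (comp == 0).any():
            j = int(np.flatnonzero(comp == 0)[0]) + i + 1
            raise ValueError(
                f"no comparable columns between {aln.ids[i]} and {aln.ids[j]}"
            )
        mism = ((chars[i] != chars[i + 1 :]) & both).sum(axis=1)
        d[i, i + 1 :] = d[i + 1 :, i] = mism / comp
    return d


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(d: np.ndarray, labels: list[str]) -> PhyloTree:
    """Classic Saitou-Nei NJ.

    Negative limb lengths are clamped to zero with the deficit shifted onto
    the sister limb, preserving the joined pair's summed length.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    if n < 3:
        raise ValueError("need at least three taxa")
    if len(labels) != n:
        raise ValueError("labels must match matrix size")

    nodes = [PhyloNode(name=l) for l in labels]
    active = list(range(n))
    D = d.copy()

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(q), q.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        a, b = active[i_], active[j_]
        dij = sub[i_, j_]
        li = 0.5 * dij + (r[i_] - r[j_]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        nodes[a].branch_length = li
        nodes[b].branch_length = lj
        parent = PhyloNode(children=[nodes[a], nodes[b]])
        new_row = 0.5 * (D[a, active] + D[b, active] - dij)
        k = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        D[k, active] = new_row
        D[active, k] = new_row
        D[k, k] = 0.0
        nodes.append(parent)
        active = [x for x in active if x not in (a, b)] + [k]

    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    nodes[a].branch_length = max((dab + dac - dbc) / 2, 0.0)
    nodes[b].branch_length = max((dab + dbc - dac) / 2, 0.0)
    nodes[c].branch_length = max((dac + dbc - dab) / 2, 0.0)
    root = PhyloNode(children=[nodes[a], nodes[b], nodes[c]])
    return PhyloTree(root)


def nj_tree(aln: MultipleAlignment) -> PhyloTree:
    return neighbor_joining(p_distance_matrix(aln), list(aln.ids))


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_support(
    aln: MultipleAlignment, n_replicates: int = 1000, seed: int = 0
) -> PhyloTree:
    """NJ tree with bootstrap supports from column resampling."""
    if aln.n_columns < 2:
        raise ValueError("alignment must have at least two columns")
    tree = nj_tree(aln)
    if n_replicates <= 0:
        return tree
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    n_cols = aln.n_columns
    for _ in range(n_replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        rows = ["".join(r[c] for c in cols) for r in aln.rows]
        rep = nj_tree(MultipleAlignment(list(aln.ids), rows))
        for split in rep.bipartitions():
            counts[split] = counts.get(split, 0) + 1
    for split, node in tree.bipartitions().items():
        node.support = 100.0 * counts.get(split, 0) / n_replicates
    return tree


# ---------------------------------------------------------------------------
# group assignment


def assign_groups(
    tree: PhyloTree, reference_labels: dict[str, str]
) -> dict[str, str]:
    """Assign each non-reference leaf the group of its smallest enclosing
    clade that contains a reference leaf, over all rootings.

    Every tree edge defines a candidate clade (the member-side component
    when the edge is cut); the smallest one containing at least one labeled
    reference leaf decides: a unanimous reference group is assigned,
    a mixed clade leaves the member ungrouped.
    """
    all_leaves = tree.leaf_names()
    refs = set(reference_labels) & all_leaves
    if not refs:
        raise ValueError("tree contains no labeled reference leaves")
    members = sorted(all_leaves - set(reference_labels))

    # every edge = one node (side below it) plus its complement
    sides: list[frozenset[str]] = []
    for node in tree.root.walk():
        if node is tree.root:
            continue
        below = node.leaf_names()
        sides.append(below)
        sides.append(all_leaves - below)

    out: dict[str, str] = {}
    for m in members:
        candidates = [
            s for s in sides if m in s and any(r in s for r in refs)
        ]
        best = min(candidates, key=lambda s: (len(s), tuple(sorted(s))))
        groups = {reference_labels[r] for r in best & refs}
        out[m] = groups.pop() if len(groups) == 1 else UNGROUPED
    return out
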