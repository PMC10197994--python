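import numpy as np
import pytest

from cdpksurvey import phylo
from cdpksurvey.msa import MultipleAlignment
from cdpksurvey.phylo import PhyloNode, PhyloTree


def random_additive_tree(rng, n_leaves):
    """Random binary unrooted tree; returns (tree, labels, distance matrix,
    bipartitions) with distances from summed branch lengths."""
    labels = [f"L{i}" for i in range(n_leaves)]
    nodes = [PhyloNode(name=l, branch_length=rng.uniform(0.05, 1.0))
             for l in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = PhyloNode(children=[nodes[i], nodes[j]],
                           branch_length=rng.uniform(0.05, 1.0))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = PhyloTree(PhyloNode(children=nodes))
    # distances by walking leaf-to-root paths
    paths = {}

    def walk(node, acc):
        acc = acc + [node]
        if node.is_leaf:
            paths[node.name] = acc
        for c in node.children:
            walk(c, acc)

    walk(tree.root, [])
    d = np.zeros((n_leaves, n_leaves))
    for a in range(n_leaves):
        for b in range(a + 1, n_leaves):
            pa, pb = paths[labels[a]], paths[labels[b]]
            shared = sum(1 for x, y in zip(pa, pb) if x is y)
            dist = sum(n.branch_length for n in pa[shared:]) + sum(
                n.branch_length for n in pb[shared:]
            )
            d[a, b] = d[b, a] = dist
    return tree, labels, d


def tree_leaf_distances(tree: PhyloTree):
    """Pairwise path-length distances between all leaves (test-side walk)."""
    paths = {}

    def walk(node, acc):
        acc = acc + [node]
        if node.is_leaf:
            paths[node.name] = acc
        for c in node.children:
            walk(c, acc)

    walk(tree.root, [])
    out = {}
    for a in paths:
        for b in paths:
            if a >= b:
                continue
            pa, pb = paths[a], paths[b]
            shared = sum(1 for x, y in zip(pa, pb) if x is y)
            out[(a, b)] = sum(n.branch_length for n in pa[shared:]) + sum(
                n.branch_length for n in pb[shared:]
            )
    return out


class TestPDistance:
    def test_identical_rows_have_zero_distance(self):
        aln = MultipleAlignment(["a", "b", "c"], ["MKV", "MKV", "MKV"])
        assert phylo.p_distance_matrix(aln).max() == 0.0

    def test_closed_form_quarter(self):
        aln = MultipleAlignment(["a", "b", "c"], ["AAAA", "AAAT", "CCCC"])
        d = phylo.p_distance_matrix(aln)
        assert d[0, 1] == pytest.approx(0.25)
        assert d[0, 2] == pytest.approx(1.0)

    def test_gap_columns_are_pairwise_deleted(self):
        aln = MultipleAlignment(["a", "b", "c"], ["A-AA", "ATAA", "TTTT"])
        d = phylo.p_distance_matrix(aln)
        assert d[0, 1] == pytest.approx(0.0)  # 3 comparable, 0 mismatch

    def test_matches_per_pair_recount_oracle(self):
        rng = np.random.default_rng(5)
        letters = np.array(list("ACDE-"))
        rows = ["".join(rng.choice(letters, size=60)) for _ in range(6)]
        ids = [f"s{i}" for i in range(6)]
        d = phylo.p_distance_matrix(MultipleAlignment(ids, rows))
        for i in range(6):
            for j in range(6):
                comp = mism = 0
                for x, y in zip(rows[i], rows[j]):
                    if x != "-" and y != "-":
                        comp += 1
                        mism += x != y
                assert d[i, j] == pytest.approx(mism / comp)

    def test_incomparable_pair_is_error(self):
        aln = MultipleAlignment(["a", "b", "c"], ["A-", "-A", "AA"])
        with pytest.raises(ValueError, match="comparable"):
            phylo.p_distance_matrix(aln)


class TestNeighborJoining:
    def test_three_leaf_closed_form(self):
        d = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        tree = phylo.neighbor_joining(d, ["a", "b", "c"])
        bl = {l.name: l.branch_length for l in tree.root.leaves()}
        assert bl["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2, abs=1e-12)
        assert bl["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2, abs=1e-12)
        assert bl["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2, abs=1e-12)

    def test_additive_matrices_recover_topology_and_lengths(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(6, 11))
            true_tree, labels, d = random_additive_tree(rng, n)
            rec = phylo.neighbor_joining(d, labels)
            assert set(rec.bipartitions()) == set(true_tree.bipartitions())
            rec_d = tree_leaf_distances(rec)
            for (a, b), dist in rec_d.items():
                ia, ib = labels.index(a), labels.index(b)
                assert dist == pytest.approx(d[ia, ib], abs=1e-9)

    def test_input_order_invariance_of_topology(self):
        rng = np.random.default_rng(13)
        _, labels, d = random_additive_tree(rng, 8)
        t1 = phylo.neighbor_joining(d, labels)
        perm = rng.permutation(8)
        t2 = phylo.neighbor_joining(
            d[np.ix_(perm, perm)], [labels[i] for i in perm]
        )
        assert set(t1.bipartitions()) == set(t2.bipartitions())

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1.0, 2], [1.1, 0, 1], [2, 1, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            phylo.neighbor_joining(d, list("abc"))


def _two_clade_alignment(rng, n_per_clade=5, n_cols=120, rate=0.05):
    base_a = rng.choice(list("ACDEFGHIKLMN"), size=n_cols)
    base_b = rng.choice(list("PQRSTVWY"), size=n_cols)
    ids, rows = [], []
    for k, base in (("A", base_a), ("B", base_b)):
        for i in range(n_per_clade):
            row = base.copy()
            mask = rng.random(n_cols) < rate
            row[mask] = rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=mask.sum())
            ids.append(f"{k}{i}")
            rows.append("".join(row))
    return MultipleAlignment(ids, rows)


class TestBootstrap:
    def test_strong_split_gets_high_support(self):
        rng = np.random.default_rng(17)
        aln = _two_clade_alignment(rng)
        tree = phylo.bootstrap_support(aln, n_replicates=100, seed=1)
        clade_a = frozenset(i for i in aln.ids if i.startswith("A"))
        all_l = frozenset(aln.ids)
        supports = {
            s: n.support for s, n in tree.bipartitions().items()
            if n.support is not None
        }
        split = clade_a if min(all_l) not in clade_a else all_l - clade_a
        assert supports.get(split, 0) >= 95

    def test_zero_replicates_leave_supports_absent(self):
        rng = np.random.default_rng(19)
        aln = _two_clade_alignment(rng)
        tree = phylo.bootstrap_support(aln, n_replicates=0)
        assert all(n.support is None for n in tree.root.walk())

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(23)
        aln = _two_clade_alignment(rng)
        t1 = phylo.bootstrap_support(aln, n_replicates=50, seed=9)
        t2 = phylo.bootstrap_support(aln, n_replicates=50, seed=9)
        s1 = {s: n.support for s, n in t1.bipartitions().items()}
        s2 = {s: n.support for s, n in t2.bipartitions().items()}
        assert s1 == s2


def _tree(newick_like):
    """Tiny hand-built trees for group assignment tests."""
    return newick_like


class TestAssignGroups:
    def _build(self):
        # ((m1, r1), (r2, r3)) with r1 in II, r2/r3 in I
        m1 = PhyloNode(name="m1", branch_length=0.1)
        r1 = PhyloNode(name="r1", branch_length=0.1)
        r2 = PhyloNode(name="r2", branch_length=0.1)
        r3 = PhyloNode(name="r3", branch_length=0.1)
        inner1 = PhyloNode(children=[m1, r1], branch_length=0.2)
        inner2 = PhyloNode(children=[r2, r3], branch_length=0.2)
        out = PhyloNode(name="r4", branch_length=0.5)
        return PhyloTree(PhyloNode(children=[inner1, inner2, out]))

    def test_member_sister_to_single_reference_gets_its_group(self):
        tree = self._build()
        labels = {"r1": "II", "r2": "I", "r3": "I", "r4": "III"}
        assert phylo.assign_groups(tree, labels)["m1"] == "II"

    def test_mixed_smallest_clade_leaves_member_ungrouped(self):
        # the smallest clade containing m1 and a reference is {m1, r1, r2},
        # which mixes groups I and III
        m1 = PhyloNode(name="m1", branch_length=0.1)
        r1 = PhyloNode(name="r1", branch_length=0.1)
        r2 = PhyloNode(name="r2", branch_length=0.1)
        cherry = PhyloNode(children=[r1, r2], branch_length=0.2)
        inner_x = PhyloNode(children=[m1, cherry], branch_length=0.2)
        r3 = PhyloNode(name="r3", branch_length=0.1)
        r4 = PhyloNode(name="r4", branch_length=0.1)
        r5 = PhyloNode(name="r5", branch_length=0.1)
        inner_y = PhyloNode(
            children=[r3, PhyloNode(children=[r4, r5], branch_length=0.2)],
            branch_length=0.2,
        )
        tree = PhyloTree(PhyloNode(children=[inner_x, inner_y]))
        labels = {"r1": "I", "r2": "III", "r3": "II", "r4": "II", "r5": "II"}
        assert phylo.assign_groups(tree, labels)["m1"] == "ungrouped"

    def test_never_assigns_group_absent_from_references(self):
        tree = self._build()
        labels = {"r1": "II", "r2": "I", "r3": "I", "r4": "III"}
        got = set(phylo.assign_groups(tree, labels).values())
        assert got <= set(labels.values()) | {"ungrouped"}

    def test_tree_without_references_is_error(self):
        tree = self._build()
        with pytest.raises(ValueError, match="reference"):
            phylo.assign_groups(tree, {"zz": "I"})

    def test_supports_invariant_to_leaf_relabeling(self):
        rng = np.random.default_rng(29)
        aln = _two_clade_alignment(rng)
        t1 = phylo.bootstrap_support(aln, n_replicates=50, seed=2)
        mapping = {i: f"x_{i}" for i in aln.ids}
        aln2 = MultipleAlignment([mapping[i] for i in aln.ids], list(aln.rows))
        t2 = phylo.bootstrap_support(aln2, n_replicates=50, seed=2)
        s1 = {
            frozenset(mapping[x] for x in s): n.support
            for s, n in t1.bipartitions().items()
        }
        s2 = {s: n.support for s, n in t2.bipartitions().items()}
        assert s1 == s2


class TestNewick:
    def test_round_trip_through_written_file(self, tmp_path):
        d = np.array([[0, 0.3, 0.5, 0.4], [0.3, 0, 0.6, 0.5],
                      [0.5, 0.6, 0, 0.3], [0.4, 0.5, 0.3, 0]])
        tree = phylo.neighbor_joining(d, list("abcd"))
        p = tmp_path / "t.nwk"
        tree.write_newick(p)
        text = p.read_text().strip()
        assert text.startswith("(") and text.endswith(");")
        for leaf in "abcd":
            assert leaf in text
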