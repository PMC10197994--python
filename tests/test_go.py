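import networkx as nx
import numpy as np
import pytest

from cdpksurvey import go

from _oracles import hypergeom_upper_tail, reachability_closure


class TestHypergeometric:
    def test_zero_successes_gives_p_one(self):
        assert go.hypergeometric_test(0, 10, 20, 100) == 1.0

    def test_forced_overlap_gives_p_one(self):
        assert go.hypergeometric_test(5, 5, 5, 5) == 1.0

    def test_matches_enumeration_oracle_on_toy_grid(self):
        cases = [(6, 10, 20, 100)]
        rng = np.random.default_rng(2)
        for _ in range(40):
            N = int(rng.integers(5, 201))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            lo = max(0, n + K - N)
            k = int(rng.integers(lo, min(n, K) + 1))
            cases.append((k, n, K, N))
        for k, n, K, N in cases:
            assert go.hypergeometric_test(k, n, K, N) == pytest.approx(
                hypergeom_upper_tail(k, n, K, N), abs=1e-12
            )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            go.hypergeometric_test(11, 10, 20, 100)
        with pytest.raises(ValueError):
            go.hypergeometric_test(0, 10, 95, 100)  # k < n + K - N


def _toy_dag():
    dag = nx.DiGraph()
    rows = [
        ("leafA", "mid1", "BP"), ("leafB", "mid1", "BP"),
        ("leafC", "mid2", "BP"), ("mid1", "root", "BP"),
        ("mid2", "root", "BP"),
    ]
    for c, p, ns in rows:
        dag.add_edge(c, p)
        dag.nodes[c]["namespace"] = ns
        dag.nodes[p]["namespace"] = ns
    return dag


class TestPropagation:
    def test_leaf_annotation_counts_at_every_ancestor(self):
        dag = _toy_dag()
        out = go.annotate_up_propagate({"g1": {"leafA"}}, dag)
        assert out["g1"] == {"leafA", "mid1", "root"}

    def test_root_annotation_stays_root(self):
        dag = _toy_dag()
        out = go.annotate_up_propagate({"g1": {"root"}}, dag)
        assert out["g1"] == {"root"}

    def test_unknown_term_warns_and_skips(self):
        dag = _toy_dag()
        with pytest.warns(UserWarning, match="unknown"):
            out = go.annotate_up_propagate({"g1": {"nope", "leafB"}}, dag)
        assert out["g1"] == {"leafB", "mid1", "root"}

    def test_closure_matches_reachability_oracle(self):
        rng = np.random.default_rng(9)
        n = 20
        # random DAG: edges only from lower to higher index
        edges = []
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.15:
                    edges.append((i, j))
        dag = nx.DiGraph()
        dag.add_nodes_from(range(n))
        dag.add_edges_from(edges)
        reach = reachability_closure(n, edges)
        ann = {f"g{i}": {i} for i in range(n)}
        out = go.annotate_up_propagate(ann, dag)
        for i in range(n):
            expected = {i} | {j for j in range(n) if reach[i][j]}
            assert out[f"g{i}"] == expected


class TestElim:
    def test_flat_dag_elim_equals_raw(self):
        dag = nx.DiGraph()
        dag.add_nodes_from(["t1", "t2", "t3"])
        ann = {f"g{i}": {"t1"} for i in range(5)}
        ann.update({f"h{i}": {"t2"} for i in range(5)})
        ann.update({f"x{i}": {"t3"} for i in range(10)})
        study = {"g0", "g1", "g2", "h0"}
        results = go.elim_enrichment(study, set(ann), ann, dag)
        for r in results:
            assert r.p_elim == r.p_raw

    def test_parent_sharing_genes_with_significant_child_loses_signal(self):
        dag = nx.DiGraph()
        dag.add_edge("child", "parent")
        population = {f"g{i}" for i in range(40)}
        ann = {}
        for i in range(40):
            # ten genes carry the child (and therefore the parent)
            ann[f"g{i}"] = {"child"} if i < 10 else set()
        study = {f"g{i}" for i in range(8)}  # all child genes
        results = {r.term: r for r in go.elim_enrichment(
            study, population, ann, dag, alpha=0.05
        )}
        assert results["child"].p_elim < 0.05
        assert results["parent"].p_elim >= results["parent"].p_raw

    def test_three_level_dag_matches_hand_stepped_oracle(self):
        # leaf -> mid -> root; signal planted at the leaf
        dag = nx.DiGraph()
        dag.add_edge("leaf", "mid")
        dag.add_edge("mid", "root")
        population = {f"g{i}" for i in range(30)}
        ann = {}
        for i in range(30):
            if i < 6:
                ann[f"g{i}"] = {"leaf"}
            elif i < 12:
                ann[f"g{i}"] = {"mid"}
            else:
                ann[f"g{i}"] = {"root"}
        study = {"g0", "g1", "g2", "g3", "g4"}  # five of six leaf genes
        results = {r.term: r for r in go.elim_enrichment(
            study, population, ann, dag, alpha=0.05
        )}
        # manual stepwise recomputation of the elim sequence:
        # 1. leaf tested on its 6 genes, 5 in study
        p_leaf = hypergeom_upper_tail(5, 5, 6, 30)
        assert results["leaf"].p_elim == pytest.approx(p_leaf, abs=1e-12)
        assert p_leaf < 0.05
        # 2. leaf is significant -> its genes leave mid's and root's lists:
        #    mid keeps its own 6 genes, none in study
        p_mid = hypergeom_upper_tail(0, 5, 6, 30)
        assert results["mid"].p_elim == pytest.approx(p_mid, abs=1e-12)
        # 3. root keeps 30 - 6 = 24 genes, 0 in study
        p_root = hypergeom_upper_tail(0, 5, 24, 30)
        assert results["root"].p_elim == pytest.approx(p_root, abs=1e-12)
        # raw pass has the full propagated lists
        assert results["mid"].p_raw == pytest.approx(
            hypergeom_upper_tail(5, 5, 12, 30), abs=1e-12
        )
        assert results["root"].p_raw == pytest.approx(
            hypergeom_upper_tail(5, 5, 30, 30), abs=1e-12
        )

    def test_elim_never_reports_more_significant_terms_than_raw(self, bundle):
        dag = go.load_ontology(bundle.ontology_path)
        ann = go.load_annotations(bundle.annotations_path)
        population = set(ann)
        rng = np.random.default_rng(3)
        study = set(rng.choice(sorted(population), size=20, replace=False))
        results = go.elim_enrichment(study, population, ann, dag)
        n_sig_elim = sum(r.p_elim < 0.05 for r in results)
        n_sig_raw = sum(r.p_raw < 0.05 for r in results)
        assert n_sig_elim <= n_sig_raw

    def test_results_invariant_to_gene_order(self, bundle):
        dag = go.load_ontology(bundle.ontology_path)
        ann = go.load_annotations(bundle.annotations_path)
        population = set(ann)
        study = set(sorted(population)[:15])
        r1 = go.elim_enrichment(study, population, ann, dag)
        shuffled = dict(reversed(list(ann.items())))
        r2 = go.elim_enrichment(study, population, shuffled, dag)
        assert r1 == r2

    def test_study_must_be_subset_of_population(self):
        with pytest.raises(ValueError, match="subset"):
            go.elim_enrichment({"a"}, {"b"}, {}, nx.DiGraph())

    def test_cyclic_ontology_rejected(self, tmp_path):
        p = tmp_path / "cyc.tsv"
        p.write_text("a\tb\tBP\nb\ta\tBP\n")
        with pytest.raises(ValueError, match="cycle"):
            go.load_ontology(p)
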