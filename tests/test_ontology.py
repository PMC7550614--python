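"""Wang semantic similarity, OBO parsing, and over-representation."""

import math
from itertools import combinations

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pesignet.ontology import (
    OntologyDag,
    SemSimConfig,
    _bma,
    gene_sim,
    ora,
    parse_obo_subset,
    set_sim,
    term_sim,
    wang_svalues,
)


class TestParseObo:
    def _parse(self, tmp_path, text):
        p = tmp_path / "t.obo"
        p.write_text(text)
        return parse_obo_subset(p)

    def test_two_term_file(self, tmp_path):
        dag = self._parse(tmp_path, (
            "format-version: 1.2\n\n"
            "[Term]\nid: T:1\nname: root\n\n"
            "[Term]\nid: T:2\nname: child\nis_a: T:1\n"
        ))
        assert set(dag.terms) == {"T:1", "T:2"}
        assert dag.graph["T:2"]["T:1"]["relation"] == "is_a"

    def test_part_of_relationship_typed(self, tmp_path):
        dag = self._parse(tmp_path, (
            "[Term]\nid: T:1\nname: root\n\n"
            "[Term]\nid: T:2\nname: part\nrelationship: part_of T:1\n"
        ))
        assert dag.graph["T:2"]["T:1"]["relation"] == "part_of"

    def test_cycle_raises(self, tmp_path):
        with pytest.raises(ValueError, match="cycle"):
            self._parse(tmp_path, (
                "[Term]\nid: T:1\nname: a\nis_a: T:2\n\n"
                "[Term]\nid: T:2\nname: b\nis_a: T:1\n"
            ))

    def test_dangling_parent_raises(self, tmp_path):
        with pytest.raises(ValueError, match="dangling"):
            self._parse(tmp_path, "[Term]\nid: T:2\nname: x\nis_a: T:99\n")

    def test_roundtrip_with_writer(self, tmp_path):
        from pesignet.io import write_obo
        from pesignet.simulate import simulate_ontology

        dag, _ = simulate_ontology(25, part_of_fraction=0.3, seed=5)
        path = write_obo(dag, tmp_path / "sim.obo")
        back = parse_obo_subset(path)
        assert set(back.terms) == set(dag.terms)
        assert set(back.graph.edges) == set(dag.graph.edges)
        for u, v in dag.graph.edges:
            assert back.graph[u][v]["relation"] == dag.graph[u][v]["relation"]


def _chain_dag():
    g = nx.DiGraph()
    for t in ("root", "B", "A"):
        g.add_node(t, name=t, namespace="biological_process")
    g.add_edge("A", "B", relation="is_a")
    g.add_edge("B", "root", relation="is_a")
    return OntologyDag(g)


class TestWang:
    def test_s_value_of_term_itself_is_one(self, tiny_dag):
        assert wang_svalues("B", tiny_dag)["B"] == 1.0

    def test_chain_hand_recursion(self):
        dag = _chain_dag()
        s = wang_svalues("A", dag)
        assert s == pytest.approx({"A": 1.0, "B": 0.8, "root": 0.64})
        assert sum(s.values()) == pytest.approx(2.44)

    def test_part_of_weight(self):
        g = nx.DiGraph()
        g.add_node("root", name="root")
        g.add_node("A", name="A")
        g.add_edge("A", "root", relation="part_of")
        s = wang_svalues("A", OntologyDag(g))
        assert s["root"] == pytest.approx(0.6)

    def test_self_similarity_one(self, tiny_dag):
        for t in tiny_dag.terms:
            assert term_sim(t, t, tiny_dag) == pytest.approx(1.0)

    def test_sibling_similarity_hand_computed(self, tiny_dag):
        # siblings B' (here C) and A both under root via is_a:
        # (0.8 + 0.8) / (1.8 + 1.8) = 0.4444
        assert term_sim("A", "C", tiny_dag) == pytest.approx(0.444444, abs=1e-6)

    def test_disconnected_roots_similarity_zero(self):
        g = nx.DiGraph()
        for t in ("r1", "r2", "a", "b"):
            g.add_node(t, name=t)
        g.add_edge("a", "r1", relation="is_a")
        g.add_edge("b", "r2", relation="is_a")
        dag = OntologyDag(g)
        assert term_sim("a", "b", dag) == 0.0

    def test_cross_namespace_rejected(self):
        g = nx.DiGraph()
        g.add_node("a", name="a", namespace="biological_process")
        g.add_node("b", name="b", namespace="molecular_function")
        dag = OntologyDag(g)
        with pytest.raises(ValueError, match="namespace"):
            term_sim("a", "b", dag)

    def test_unknown_term_rejected(self, tiny_dag):
        with pytest.raises(KeyError):
            wang_svalues("nope", tiny_dag)

    @pytest.mark.parametrize("seed", range(8))
    def test_svalues_match_path_product_oracle(self, seed):
        # brute force: S(ancestor) = max over all directed paths of the
        # product of edge weights along the path
        from pesignet.simulate import simulate_ontology

        dag, _ = simulate_ontology(14, max_depth=4, part_of_fraction=0.4, seed=seed)
        cfg = SemSimConfig()
        for term in dag.terms:
            s = wang_svalues(term, dag, cfg)
            for anc in dag.ancestor_closure(term):
                best = 1.0 if anc == term else max(
                    math.prod(
                        cfg.weight(dag.graph[u][v]["relation"])
                        for u, v in zip(path, path[1:])
                    )
                    for path in nx.all_simple_paths(dag.graph, term, anc)
                )
                assert s[anc] == pytest.approx(best)

    def test_similarity_symmetric_and_bounded(self):
        from pesignet.simulate import simulate_ontology

        dag, _ = simulate_ontology(20, seed=3)
        terms = dag.terms[:8]
        for a, b in combinations(terms, 2):
            sab, sba = term_sim(a, b, dag), term_sim(b, a, dag)
            assert sab == pytest.approx(sba)
            assert 0.0 <= sab <= 1.0


class TestGeneSetSim:
    ANN = {"g1": {"A"}, "g2": {"C"}, "g3": {"A", "C"}}

    def test_identical_annotations_similarity_one(self, tiny_dag):
        assert gene_sim("g3", "g3", self.ANN, tiny_dag) == pytest.approx(1.0)

    def test_bma_hand_matrix(self):
        mat = np.array([[0.9, 0.7], [0.5, 0.3]])
        assert _bma(mat) == pytest.approx(0.75)

    def test_one_by_one_matrix_reduces_to_entry(self):
        assert _bma(np.array([[0.37]])) == pytest.approx(0.37)

    def test_bma_hand_2x1(self):
        assert _bma(np.array([[0.8], [0.4]])) == pytest.approx((0.8 + 0.4 + 0.8) / 3)

    def test_unannotated_gene_rejected(self, tiny_dag):
        with pytest.raises(KeyError, match="annotations"):
            gene_sim("g1", "zz", self.ANN, tiny_dag)

    def test_set_self_similarity_one(self, tiny_dag):
        assert set_sim(["g1", "g2"], ["g1", "g2"], self.ANN, tiny_dag) == pytest.approx(1.0)

    def test_singleton_sets_reduce_to_gene_sim(self, tiny_dag):
        assert set_sim(["g1"], ["g2"], self.ANN, tiny_dag) == pytest.approx(
            gene_sim("g1", "g2", self.ANN, tiny_dag)
        )

    def test_no_annotated_genes_rejected(self, tiny_dag):
        with pytest.raises(ValueError, match="annotated"):
            set_sim(["zz"], ["g1"], self.ANN, tiny_dag)

    def test_same_branch_scores_higher_than_disjoint(self):
        # two deep sibling branches under the root; gene sets annotated
        # within one branch must look more alike than sets across branches
        g = nx.DiGraph()
        g.add_node("root", name="root")
        for br in ("x", "y"):
            for i in range(3):
                g.add_node(f"{br}{i}", name=f"{br}{i}")
            g.add_edge(f"{br}0", "root", relation="is_a")
            g.add_edge(f"{br}1", f"{br}0", relation="is_a")
            g.add_edge(f"{br}2", f"{br}1", relation="is_a")
        dag = OntologyDag(g)
        ann = {"a": {"x1"}, "b": {"x2"}, "c": {"y1"}, "d": {"y2"}}
        same = set_sim(["a"], ["b"], ann, dag)
        cross = set_sim(["a"], ["c"], ann, dag)
        assert same > cross


def _ora_enumeration_oracle(universe, term_genes, sig):
    """P(overlap >= k) by exhaustive enumeration of all draws of |sig| genes."""
    from itertools import combinations as combos

    k = len(term_genes & sig)
    total = hits = 0
    for draw in combos(sorted(universe), len(sig)):
        total += 1
        if len(term_genes & set(draw)) >= k:
            hits += 1
    return hits / total


class TestOra:
    def test_hand_hypergeometric_full_overlap(self):
        # N=20, K=5, n=5, k=5 -> 1 / C(20,5)
        universe = [f"g{i}" for i in range(20)]
        ann = {g: {"T"} for g in universe[:5]}
        for g in universe[5:]:
            ann[g] = set()
        out = ora(universe[:5], universe, ann)
        assert out.loc[0, "p"] == pytest.approx(1 / 15504, rel=1e-9)

    def test_zero_overlap_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        ann = {g: {"T"} for g in universe[:4]}
        out = ora(universe[4:8], universe, ann)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_matches_enumeration_oracle_small_universe(self):
        rng = np.random.default_rng(2)
        universe = [f"g{i}" for i in range(12)]
        term_genes = set(rng.choice(universe, 5, replace=False))
        sig = set(rng.choice(universe, 6, replace=False))
        ann = {g: ({"T"} if g in term_genes else set()) for g in universe}
        out = ora(sig, universe, ann)
        want = _ora_enumeration_oracle(set(universe), term_genes, sig)
        assert out.loc[0, "p"] == pytest.approx(want, rel=1e-9)

    def test_bh_adjustment_matches_hand_formula(self):
        # build three disjoint terms with graded overlaps, then recompute
        # BH by hand from the raw p column
        rng = np.random.default_rng(5)
        universe = [f"g{i}" for i in range(40)]
        ann = {g: set() for g in universe}
        for t, members in {"T1": universe[0:8], "T2": universe[8:16],
                           "T3": universe[16:24]}.items():
            for g in members:
                ann[g].add(t)
        sig = universe[0:6] + universe[8:10] + universe[30:32]
        out = ora(sig, universe, ann).set_index("term")
        p = out["p"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        q_hand = np.empty(m)
        prev = 1.0
        for rank_pos, idx in list(enumerate(order, start=1))[::-1]:
            prev = min(prev, p[idx] * m / rank_pos)
            q_hand[idx] = prev
        np.testing.assert_allclose(out["q"].to_numpy(), q_hand)

    @settings(derandomize=True, max_examples=25)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=20))
    def test_bh_q_monotone_in_sorted_p(self, ps):
        from statsmodels.stats.multitest import multipletests

        q = multipletests(np.array(ps), method="fdr_bh")[1]
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_signature_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            ora(["x"], ["a", "b"], {"a": {"T"}})

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            ora([], [], {})

    def test_min_term_size_filters(self):
        universe = [f"g{i}" for i in range(10)]
        ann = {universe[0]: {"tiny"}, universe[1]: {"tiny"}}
        out = ora(universe[:2], universe, ann, min_term_size=3)
        assert len(out) == 0
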