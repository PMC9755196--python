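import numpy as np
import pytest

from hetlink.similarity import (
    DiseaseDAG,
    SemanticParams,
    SemanticProfile,
    SimilarityMatrix,
    build_disease_dags,
    disease_similarity,
    disease_similarity_matrix,
    integrate_mirna_similarity,
    semantic_contribution,
    similarity_to_edges,
)

from conftest import all_paths_contribution, random_rooted_dag


class TestBuildDiseaseDags:
    def test_single_chain(self):
        dags = build_disease_dags([("A", "C01.100")])
        dag = dags["A"]
        assert dag.nodes == {"A", "C01"}
        assert dag.edges == {("C01", "A")}

    def test_union_of_two_tree_numbers(self):
        dags = build_disease_dags([("X", "C01.100.200"), ("X", "C02.300.200")])
        dag = dags["X"]
        assert dag.nodes == {"X", "C01", "C01.100", "C02", "C02.300"}
        roots = {n for n in dag.nodes if not any(c == n for _p, c in dag.edges)}
        assert roots == {"C01", "C02"}

    def test_named_ancestor_is_relabelled(self):
        dags = build_disease_dags([("d", "G.P.D"), ("p", "G.P"), ("g", "G")])
        assert dags["d"].nodes == {"d", "p", "g"}
        assert ("g", "p") in dags["d"].edges and ("p", "d") in dags["d"].edges

    def test_malformed_tree_number_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            build_disease_dags([("A", "C01..100")])

    def test_ambiguous_position_rejected(self):
        with pytest.raises(ValueError, match="claimed by both"):
            build_disease_dags([("A", "C01.1"), ("B", "C01.1")])


class TestSemanticContribution:
    def test_chain(self):
        dag = DiseaseDAG("d", {"d", "p", "g"}, {("g", "p"), ("p", "d")})
        prof = semantic_contribution(dag, SemanticParams(0.5))
        assert prof.contributions == {"d": 1.0, "p": 0.5, "g": 0.25}
        assert prof.dv == pytest.approx(1.75, abs=0)

    def test_diamond_takes_max_over_paths(self):
        dag = DiseaseDAG(
            "d", {"d", "p1", "p2", "g"},
            {("g", "p1"), ("g", "p2"), ("p1", "d"), ("p2", "d")},
        )
        prof = semantic_contribution(dag, SemanticParams(0.5))
        assert prof.contributions["g"] == pytest.approx(0.25, abs=0)
        assert prof.dv == pytest.approx(2.25, abs=0)

    def test_singleton(self):
        prof = semantic_contribution(DiseaseDAG("d", {"d"}, set()))
        assert prof.contributions == {"d": 1.0}
        assert prof.dv == 1.0

    def test_cycle_reported_with_edge(self):
        dag = DiseaseDAG("d", {"d", "a", "b"}, {("a", "b"), ("b", "a"), ("a", "d")})
        with pytest.raises(ValueError, match="cycle"):
            semantic_contribution(dag)

    def test_matches_all_paths_oracle_on_random_dags(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            dag = random_rooted_dag(rng)
            delta = float(rng.choice([0.3, 0.5, 0.8]))
            prof = semantic_contribution(dag, SemanticParams(delta))
            oracle = all_paths_contribution(dag, delta)
            for t in dag.nodes:
                assert prof.contributions[t] == pytest.approx(oracle[t], abs=1e-12)
            assert prof.dv == pytest.approx(sum(oracle.values()), abs=1e-12)


class TestDiseaseSimilarity:
    def test_self_similarity_is_one(self):
        dag = DiseaseDAG("d", {"d", "p"}, {("p", "d")})
        prof = semantic_contribution(dag)
        assert disease_similarity(prof, prof) == 1.0

    def test_shared_root_third(self):
        a = semantic_contribution(DiseaseDAG("a", {"a", "R"}, {("R", "a")}))
        b = semantic_contribution(DiseaseDAG("b", {"b", "R"}, {("R", "b")}))
        assert disease_similarity(a, b) == pytest.approx(1 / 3, abs=0)

    def test_chain_parent_child_value(self):
        dags = build_disease_dags([("d", "G.P.D"), ("p", "G.P"), ("g", "G")])
        pd = semantic_contribution(dags["d"])
        pp = semantic_contribution(dags["p"])
        assert disease_similarity(pd, pp) == pytest.approx(9 / 13, abs=1e-15)

    def test_disjoint_dags_score_zero(self):
        a = semantic_contribution(DiseaseDAG("a", {"a"}, set()))
        b = semantic_contribution(DiseaseDAG("b", {"b"}, set()))
        assert disease_similarity(a, b) == 0.0

    def test_mismatched_delta_rejected(self):
        dag = DiseaseDAG("a", {"a"}, set())
        p1 = semantic_contribution(dag, SemanticParams(0.5))
        p2 = semantic_contribution(dag, SemanticParams(0.3))
        with pytest.raises(ValueError, match="delta"):
            disease_similarity(p1, p2)

    def test_symmetry_and_range_on_random_dags(self):
        # d0..dn names recur across draws, so node sets genuinely overlap
        rng = np.random.default_rng(7)
        for _ in range(50):
            p1 = semantic_contribution(random_rooted_dag(rng, 10))
            p2 = semantic_contribution(random_rooted_dag(rng, 10))
            s12 = disease_similarity(p1, p2)
            assert s12 == disease_similarity(p2, p1)
            assert 0.0 <= s12 <= 1.0

    def test_shared_ancestor_increases_similarity(self):
        # same DV by construction: one depth-1 ancestor each, shared vs not
        a_private = semantic_contribution(DiseaseDAG("a", {"a", "Ra"}, {("Ra", "a")}))
        b_private = semantic_contribution(DiseaseDAG("b", {"b", "Rb"}, {("Rb", "b")}))
        a_shared = semantic_contribution(DiseaseDAG("a", {"a", "R"}, {("R", "a")}))
        b_shared = semantic_contribution(DiseaseDAG("b", {"b", "R"}, {("R", "b")}))
        assert a_private.dv == a_shared.dv and b_private.dv == b_shared.dv
        assert disease_similarity(a_shared, b_shared) > disease_similarity(
            a_private, b_private
        )


class TestDiseaseSimilarityMatrix:
    def test_single_disease(self):
        m = disease_similarity_matrix(build_disease_dags([("A", "C01.1")]))
        assert m.ids == ["A"] and m.values.tolist() == [[1.0]]

    def test_disjoint_pair_off_diagonal_zero(self):
        m = disease_similarity_matrix(build_disease_dags([("A", "C01.1"), ("B", "C02.9")]))
        assert m.value("A", "B") == 0.0

    def test_shared_root_pair(self):
        m = disease_similarity_matrix(build_disease_dags([("A", "C01.1"), ("B", "C01.2")]))
        assert m.value("A", "B") == pytest.approx(1 / 3, abs=1e-12)
        m.validate()


class TestIntegrateMirnaSimilarity:
    @staticmethod
    def _sim(ids, off):
        n = len(ids)
        v = np.full((n, n), off, dtype=float)
        np.fill_diagonal(v, 1.0)
        return SimilarityMatrix(ids=list(ids), values=v)

    def test_mean_where_both_defined(self):
        a = self._sim(["m1", "m2"], 0.4)
        b = self._sim(["m1", "m2"], 0.6)
        out = integrate_mirna_similarity(a, b)
        assert out.value("m1", "m2") == pytest.approx(0.5, abs=0)

    def test_fallback_to_single_source(self):
        a = self._sim(["m1", "m2"], 0.7)
        b = self._sim(["m3"], 0.0)
        out = integrate_mirna_similarity(a, b)
        assert out.value("m1", "m2") == 0.7
        assert set(out.ids) == {"m1", "m2", "m3"}
        assert out.value("m1", "m3") == 0.0  # covered by neither source

    def test_idempotent_and_commutative(self):
        rng = np.random.default_rng(3)
        v = rng.uniform(0, 1, (4, 4))
        v = 0.5 * (v + v.T)
        np.fill_diagonal(v, 1.0)
        a = SimilarityMatrix(ids=list("wxyz"), values=v)
        same = integrate_mirna_similarity(a, a)
        assert np.allclose(same.values, v)
        b = self._sim(["x", "q"], 0.3)
        ab = integrate_mirna_similarity(a, b)
        ba = integrate_mirna_similarity(b, a)
        assert ab.ids == ba.ids
        assert np.allclose(ab.values, ba.values)

    def test_non_unit_diagonal_rejected(self):
        bad = SimilarityMatrix(ids=["m1"], values=np.array([[0.9]]))
        with pytest.raises(ValueError, match="diagonal"):
            integrate_mirna_similarity(bad, self._sim(["m1"], 0.0))


class TestSimilarityToEdges:
    @staticmethod
    def _three_by_three():
        v = np.full((3, 3), 0.5)
        np.fill_diagonal(v, 1.0)
        return SimilarityMatrix(ids=["a", "b", "c"], values=v)

    def test_threshold_above_one_empty(self):
        with pytest.raises(ValueError):
            similarity_to_edges(self._three_by_three(), threshold=1.1)

    def test_threshold_zero_complete_graph(self):
        edges = similarity_to_edges(self._three_by_three(), threshold=0.0)
        assert len(edges) == 3
        assert all(w == 0.5 for _a, _b, w in edges)

    def test_threshold_one_keeps_nothing_off_diagonal(self):
        edges = similarity_to_edges(self._three_by_three(), threshold=1.0)
        assert edges == []

    def test_top_k_includes_best_neighbour(self):
        v = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.2], [0.1, 0.2, 1.0]])
        edges = similarity_to_edges(
            SimilarityMatrix(ids=["a", "b", "c"], values=v), threshold=None, top_k=1
        )
        pairs = {(x, y) for x, y, _w in edges}
        assert ("a", "b") in pairs
        # brute-force: per-node best neighbours, union
        assert pairs == {("a", "b"), ("b", "c")}

    def test_bad_k_rejected(self):
        with pytest.raises(ValueError):
            similarity_to_edges(self._three_by_three(), threshold=None, top_k=0)
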