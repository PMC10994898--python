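import numpy as np
import pandas as pd
import pytest

from siggraph import (
    GraphConfig,
    SignatureGraph,
    build_candidate_edges,
    categorize_edges,
    jaccard,
    permutation_edge_test,
    reciprocal_best_hits,
    top_genes,
)
from siggraph.graph import Edge, _shuffle_matrix

from conftest import make_signature, make_sigset
from oracles import brute_force_rbh


class TestTopGenes:
    def test_sorted_by_descending_exposure(self):
        sig = make_signature("c", 3, 0, pd.Series({"g1": 3.0, "g2": 2.0, "g3": 1.0}))
        assert top_genes(sig, 2) == ["g1", "g2"]

    def test_lexicographic_tie_break(self):
        sig = make_signature("c", 3, 0, pd.Series({"g3": 1.0, "g1": 1.0, "g2": 1.0}))
        assert top_genes(sig, 2) == ["g1", "g2"]

    def test_full_set_boundary(self):
        sig = make_signature("c", 3, 0, pd.Series({"g1": 5.0, "g2": 1.0}))
        assert set(top_genes(sig, 2)) == {"g1", "g2"}
        with pytest.raises(ValueError):
            top_genes(sig, 3)


class TestJaccard:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({"x", "y"}, {"x", "y"}, 1.0),
            ({"x"}, {"y"}, 0.0),
            (set(map(str, range(1000))), set(map(str, range(500, 1500))), 1 / 3),
        ],
    )
    def test_closed_forms(self, a, b, expected):
        assert jaccard(a, b) == pytest.approx(expected)
        assert jaccard(b, a) == pytest.approx(expected)

    def test_empty_input_fatal(self):
        with pytest.raises(ValueError):
            jaccard(set(), {"x"})


def sigset_from_top_sets(cohort_id, top_sets, all_genes, **kwargs):
    """SignatureSet whose top-|set| exposures realize the given gene sets."""
    rows = []
    for s in top_sets:
        row = [2.0 if g in s else 0.0 for g in all_genes]
        rows.append(row)
    return make_sigset(cohort_id, rows, list(all_genes), **kwargs)


class TestReciprocalBestHits:
    def test_single_candidate_pair(self):
        genes = [f"g{i}" for i in range(6)]
        a = sigset_from_top_sets("A", [{"g0", "g1", "g2"}], genes)
        b = sigset_from_top_sets("B", [{"g0", "g1", "g5"}], genes, disease="t2d",
                                 disease_class="T2D", tissue="islet")
        edges = reciprocal_best_hits(a, b, GraphConfig(top_n=3))
        assert len(edges) == 1
        assert edges[0].jaccard == pytest.approx(2 / 4)
        assert edges[0].shared_genes == frozenset({"g0", "g1"})

    def test_mutual_best_matching_structure(self):
        """a1<->b1 and a2<->b2 are mutual bests; cross matches are weaker."""
        genes = [f"g{i}" for i in range(8)]
        a = sigset_from_top_sets(
            "A", [{"g0", "g1", "g2"}, {"g4", "g5", "g6"}], genes
        )
        b = sigset_from_top_sets(
            "B", [{"g0", "g1", "g7"}, {"g4", "g5", "g3"}], genes,
            disease="t2d", disease_class="T2D",
        )
        edges = reciprocal_best_hits(a, b, GraphConfig(top_n=3))
        keys = {(e.node_a.split("|")[2], e.node_b.split("|")[2]) for e in edges}
        assert keys == {("0", "0"), ("1", "1")}

    def test_same_cohort_fatal(self):
        genes = ["g0", "g1"]
        a = sigset_from_top_sets("A", [{"g0"}], genes)
        with pytest.raises(ValueError):
            reciprocal_best_hits(a, a, GraphConfig(top_n=1))

    def test_oracle_equivalence_random_instances(self, rng):
        """Edge sets equal an independent double-loop Jaccard oracle."""
        genes = [f"g{i}" for i in range(40)]
        cfg = GraphConfig(top_n=8)
        for _ in range(25):
            na, nb = rng.integers(1, 15, 2)
            mat_a = rng.uniform(0, 1, (na, 40))
            mat_b = rng.uniform(0, 1, (nb, 40))
            a = make_sigset("A", mat_a, genes)
            b = make_sigset("B", mat_b, genes, disease="t2d", disease_class="T2D")
            edges = reciprocal_best_hits(a, b, cfg)
            got = {
                (int(e.node_a.split("|")[2]), int(e.node_b.split("|")[2]))
                for e in edges
            }
            sets_a = [set(top_genes(s, 8)) for s in a]
            sets_b = [set(top_genes(s, 8)) for s in b]
            assert got == brute_force_rbh(sets_a, sets_b)

    def test_symmetric_in_arguments(self, rng):
        genes = [f"g{i}" for i in range(30)]
        a = make_sigset("A", rng.uniform(0, 1, (6, 30)), genes)
        b = make_sigset("B", rng.uniform(0, 1, (7, 30)), genes)
        cfg = GraphConfig(top_n=6)
        ab = {e.key for e in reciprocal_best_hits(a, b, cfg)}
        ba = {e.key for e in reciprocal_best_hits(b, a, cfg)}
        assert ab == ba


class TestPermutationTest:
    def test_insufficient_permutations_fatal(self):
        with pytest.raises(ValueError, match="19"):
            permutation_edge_test([], [], GraphConfig(n_permutations=10, edge_alpha=0.05))

    @pytest.mark.parametrize("occurrence", ["stronger_link", "same_pair"])
    def test_distinct_structure_edge_retained_with_min_p(self, rng, occurrence):
        """Signatures sharing a coherent gene block across cohorts whose gene
        universes otherwise differ are never matched under permutation:
        p = 1/21, retained at alpha 0.05."""
        shared = [f"shared{i:02d}" for i in range(20)]
        genes_a = shared + [f"a{i:04d}" for i in range(1980)]
        genes_b = shared + [f"b{i:04d}" for i in range(1980)]
        strong = np.zeros(2000)
        strong[:20] = 5.0
        a = make_sigset("A", [strong + rng.uniform(0, 0.1, 2000) for _ in range(2)], genes_a)
        b = make_sigset("B", [strong + rng.uniform(0, 0.1, 2000) for _ in range(2)],
                        genes_b, disease="t2d", disease_class="T2D")
        cfg = GraphConfig(top_n=20, n_permutations=20, edge_alpha=0.05, seed=1,
                          occurrence=occurrence)
        observed = build_candidate_edges([a, b], cfg)
        graph = permutation_edge_test([a, b], observed, cfg)
        assert graph.edges
        for e in graph.edges:
            assert e.permutation_p == pytest.approx(1 / 21)

    def test_any_pair_mode_rejects_always_relinking_pair(self, rng):
        """With one signature per cohort, some link between the cohort pair
        forms in every permutation under the loosest occurrence mode:
        p = 1, edge removed."""
        genes = [f"g{i}" for i in range(30)]
        a = make_sigset("A", rng.uniform(0.1, 1, (1, 30)), genes)
        b = make_sigset("B", rng.uniform(0.1, 1, (1, 30)), genes)
        cfg = GraphConfig(top_n=10, n_permutations=20, edge_alpha=0.05, seed=2,
                          occurrence="any_pair")
        observed = build_candidate_edges([a, b], cfg)
        assert len(observed) == 1
        graph = permutation_edge_test([a, b], observed, cfg)
        assert graph.edges == []

    def test_shuffle_preserves_exposure_multisets(self, rng):
        mat = rng.uniform(0, 1, (5, 12))
        out = _shuffle_matrix(mat.copy(), "within_signature", rng)
        for i in range(5):
            assert sorted(out[i]) == pytest.approx(sorted(mat[i]))
        out2 = _shuffle_matrix(mat.copy(), "whole_matrix", rng)
        assert sorted(out2.ravel()) == pytest.approx(sorted(mat.ravel()))

    def test_reproducible_given_seed(self, rng):
        genes = [f"g{i}" for i in range(40)]
        a = make_sigset("A", rng.uniform(0, 1, (4, 40)), genes)
        b = make_sigset("B", rng.uniform(0, 1, (4, 40)), genes)
        cfg = GraphConfig(top_n=10, n_permutations=20, edge_alpha=1.0, seed=9)
        observed = build_candidate_edges([a, b], cfg)
        g1 = permutation_edge_test([a, b], observed, cfg)
        g2 = permutation_edge_test([a, b], observed, cfg)
        assert [e.permutation_p for e in g1.edges] == [e.permutation_p for e in g2.edges]


def graph_with_edge(class_a, class_b, disease_a, disease_b, tissue_a="brain", tissue_b="islet"):
    nodes = {
        "A|k2|0": {"cohort_id": "A", "rank_k": 2, "index_in_rank": 0,
                   "disease": disease_a, "disease_class": class_a, "tissue": tissue_a,
                   "diagnosis_p": 0.01},
        "B|k2|0": {"cohort_id": "B", "rank_k": 2, "index_in_rank": 0,
                   "disease": disease_b, "disease_class": class_b, "tissue": tissue_b,
                   "diagnosis_p": 0.01},
    }
    edge = Edge("A|k2|0", "B|k2|0", "A", "B", 0.5, frozenset({"G1"}), 0.047)
    return SignatureGraph(nodes=nodes, edges=[edge])


class TestCategorizeEdges:
    @pytest.mark.parametrize(
        "class_a, class_b, disease_a, disease_b, expected",
        [
            ("PSY", "T2D", "scz", "t2d", "inter_class_comorbid"),
            ("PSY", "PSY", "scz", "bd", "intra_class_comorbid"),
            ("T2D", "CVD", "t2d", "ami", "somatic"),
            ("CVD", "CVD", "cad", "cad", "single"),
        ],
    )
    def test_rule_table(self, class_a, class_b, disease_a, disease_b, expected):
        g = graph_with_edge(class_a, class_b, disease_a, disease_b)
        categorize_edges(g)
        assert g.edges[0].category == expected

    def test_tissue_relation(self):
        g = graph_with_edge("CVD", "CVD", "cad", "cad", tissue_a="vessel", tissue_b="vessel")
        categorize_edges(g)
        assert g.edges[0].tissue_relation == "same_tissue"
        g2 = graph_with_edge("CVD", "CVD", "cad", "cad")
        categorize_edges(g2)
        assert g2.edges[0].tissue_relation == "cross_tissue"

    def test_unknown_class_fatal(self):
        g = graph_with_edge("XXX", "T2D", "foo", "t2d")
        with pytest.raises(ValueError, match="unknown disease class"):
            categorize_edges(g)

    def test_categories_partition_edges(self, rng):
        """Each edge receives exactly one category; summary counts sum to total."""
        import itertools
        diseases = [("scz", "PSY"), ("bd", "PSY"), ("t2d", "T2D"), ("ami", "CVD")]
        nodes, edges = {}, []
        for i, (d, c) in enumerate(diseases):
            nodes[f"C{i}|k2|0"] = {
                "cohort_id": f"C{i}", "rank_k": 2, "index_in_rank": 0,
                "disease": d, "disease_class": c,
                "tissue": rng.choice(["brain", "blood"]), "diagnosis_p": 0.01,
            }
        for (i, _), (j, _) in itertools.combinations(enumerate(diseases), 2):
            edges.append(
                Edge(f"C{i}|k2|0", f"C{j}|k2|0", f"C{i}", f"C{j}", 0.2, frozenset(), 0.047)
            )
        g = SignatureGraph(nodes=nodes, edges=edges)
        categorize_edges(g)
        assert all(e.category is not None for e in g.edges)
        assert int(g.category_summary()["n_edges"].sum()) == len(edges)


def test_graph_json_round_trip_structure(rng):
    g = graph_with_edge("PSY", "T2D", "scz", "t2d")
    categorize_edges(g)
    import json
    d = json.loads(g.to_json())
    assert set(d) == {"nodes", "edges"}
    assert d["edges"][0]["category"] == "inter_class_comorbid"
    assert d["edges"][0]["shared_genes"] == ["G1"]
    table = g.edge_table()
    assert list(table["edge_id"]) == ["A|k2|0--B|k2|0"]
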