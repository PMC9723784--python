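"""Tripartite graph construction, case classification, prediction, export."""

import networkx as nx
import pytest

from lignolink.knowledge import EnzymeRecord, GenomeAnnotation
from lignolink.network import (
    TripartiteError,
    build_tripartite,
    check_tripartite,
    classify_cases,
    export_graph,
    import_graphml,
    predict_enzymes,
    summarize_graph,
)
from lignolink.similarity import SimilarityEdge


def enzyme(eid, *substrates):
    return EnzymeRecord(id=eid, name=eid, substrates=tuple(substrates))


ANNOTATION = GenomeAnnotation(
    counts={"MAG1": {"e1": 2, "e2": 1}, "MAG4": {"e2": 3}}
)


class TestBuild:
    def test_minimal_motif(self):
        g = build_tripartite(
            [SimilarityEdge("p1", "l1", 0.8)], [enzyme("e1", "l1")], ANNOTATION
        )
        assert set(g.nodes) == {"p1", "l1", "e1"}
        assert g.edges["p1", "l1"]["type"] == "similarity"
        assert g.edges["p1", "l1"]["weight"] == 0.8
        assert g.edges["l1", "e1"]["type"] == "catalysis"
        assert g.nodes["e1"]["gene_counts"] == {"MAG1": 2, "MAG4": 0}

    def test_empty_edge_list_keeps_catalysis_backbone_only(self):
        g = build_tripartite([], [enzyme("e1", "l1"), enzyme("e2", "l2")], ANNOTATION)
        partitions = nx.get_node_attributes(g, "partition")
        assert sorted(p for p in partitions.values()) == ["ENZ", "ENZ", "LDCC", "LDCC"]
        assert all(d["type"] == "catalysis" for *_, d in g.edges(data=True))

    def test_drop_isolated_false_keeps_all_catalog_pdcc(self):
        g = build_tripartite(
            [SimilarityEdge("p1", "l1", 0.7)],
            [enzyme("e1", "l1")],
            ANNOTATION,
            all_pdcc_ids=["p1", "p2"],
            drop_isolated=False,
        )
        assert g.nodes["p2"]["partition"] == "PDCC"
        assert g.degree["p2"] == 0

    def test_unknown_annotation_enzyme_warns_not_fatal(self, caplog):
        ann = GenomeAnnotation(counts={"MAG1": {"ghost": 1}})
        with caplog.at_level("WARNING"):
            build_tripartite([SimilarityEdge("p1", "l1", 0.9)], [enzyme("e1", "l1")], ann)
        assert "ghost" in caplog.text

    def test_forbidden_edges_detected(self):
        g = nx.Graph()
        g.add_node("p1", partition="PDCC")
        g.add_node("e1", partition="ENZ")
        g.add_edge("p1", "e1", type="similarity")
        with pytest.raises(TripartiteError, match="forbidden"):
            check_tripartite(g)

    def test_self_loop_detected(self):
        g = nx.Graph()
        g.add_node("l1", partition="LDCC")
        g.add_edge("l1", "l1", type="catalysis")
        with pytest.raises(TripartiteError, match="self-loop"):
            check_tripartite(g)


class TestClassifyCases:
    def test_case_i_single_ldcc_single_enzyme(self):
        g = build_tripartite(
            [SimilarityEdge("p1", "l1", 0.7)], [enzyme("e1", "l1")], ANNOTATION
        )
        report = classify_cases(g)
        assert report.labels["p1"] == {"case_i"}

    def test_case_ii_two_ldcc_different_enzymes(self):
        g = build_tripartite(
            [SimilarityEdge("p1", "l1", 0.7), SimilarityEdge("p1", "l2", 0.8)],
            [enzyme("e1", "l1"), enzyme("e2", "l2")],
            ANNOTATION,
        )
        assert classify_cases(g).labels["p1"] == {"case_ii"}

    def test_case_iii_two_pdcc_sharing_single_enzyme_ldcc(self):
        g = build_tripartite(
            [SimilarityEdge("p1", "l1", 0.7), SimilarityEdge("p2", "l1", 0.9)],
            [enzyme("e1", "l1")],
            ANNOTATION,
        )
        report = classify_cases(g)
        assert "case_iii_member" in report.labels["p1"]
        assert "case_iii_member" in report.labels["p2"]
        assert report.hub_ldcc == {"l1"}

    def test_labels_are_sets_and_every_pdcc_labelled(self):
        # p1 alone on a hub LDCC also satisfies case_i
        g = build_tripartite(
            [SimilarityEdge("p1", "l1", 0.7), SimilarityEdge("p2", "l1", 0.9)],
            [enzyme("e1", "l1")],
            ANNOTATION,
        )
        report = classify_cases(g)
        for pid in ("p1", "p2"):
            assert report.labels[pid] >= {"case_i", "case_iii_member"}

    def test_unclassified_when_no_motif_matches(self):
        # one LDCC with two enzymes: neither case i nor ii nor iii
        g = build_tripartite(
            [SimilarityEdge("p1", "l1", 0.7)],
            [enzyme("e1", "l1"), enzyme("e2", "l1")],
            ANNOTATION,
        )
        assert classify_cases(g).labels["p1"] == {"unclassified"}

    def test_counts_stable_under_relabeling(self):
        edges = [SimilarityEdge("p1", "l1", 0.7), SimilarityEdge("p1", "l2", 0.8)]
        enzymes = [enzyme("e1", "l1"), enzyme("e2", "l2")]
        g = build_tripartite(edges, enzymes, ANNOTATION)
        renamed = build_tripartite(
            [SimilarityEdge("zz_p1", "aa_l1", 0.7), SimilarityEdge("zz_p1", "aa_l2", 0.8)],
            [enzyme("qq_e1", "aa_l1"), enzyme("qq_e2", "aa_l2")],
            GenomeAnnotation(),
        )
        assert classify_cases(g).counts == classify_cases(renamed).counts


class TestPredictEnzymes:
    def test_ranking_by_similarity_then_enzyme_id(self):
        g = build_tripartite(
            [SimilarityEdge("p1", "l1", 0.8), SimilarityEdge("p1", "l2", 0.7)],
            [enzyme("e1", "l1"), enzyme("e2", "l2")],
            ANNOTATION,
        )
        preds = predict_enzymes(g, "p1")
        assert [(p.enzyme_id, p.supporting_ldcc_id, p.similarity) for p in preds] == [
            ("e1", "l1", 0.8),
            ("e2", "l2", 0.7),
        ]
        assert preds[0].gene_counts_dict() == {"MAG1": 2, "MAG4": 0}

    def test_tie_broken_lexicographically(self):
        g = build_tripartite(
            [SimilarityEdge("p1", "l1", 0.7), SimilarityEdge("p1", "l2", 0.7)],
            [enzyme("eB", "l1"), enzyme("eA", "l2")],
            ANNOTATION,
        )
        assert [p.enzyme_id for p in predict_enzymes(g, "p1")] == ["eA", "eB"]

    def test_best_supporting_ldcc_per_enzyme(self):
        g = build_tripartite(
            [SimilarityEdge("p1", "l1", 0.7), SimilarityEdge("p1", "l2", 0.9)],
            [enzyme("e1", "l1", "l2")],
            ANNOTATION,
        )
        (pred,) = predict_enzymes(g, "p1")
        assert pred.supporting_ldcc_id == "l2"
        assert pred.similarity == 0.9

    def test_pdcc_with_no_reachable_enzyme_gives_empty_list(self):
        g = build_tripartite(
            [SimilarityEdge("p1", "l_orphan", 0.9)], [enzyme("e1", "l1")], ANNOTATION
        )
        assert predict_enzymes(g, "p1") == []

    def test_unknown_or_wrong_partition_rejected(self):
        g = build_tripartite(
            [SimilarityEdge("p1", "l1", 0.7)], [enzyme("e1", "l1")], ANNOTATION
        )
        with pytest.raises(KeyError):
            predict_enzymes(g, "nope")
        with pytest.raises(ValueError, match="not a PDCC"):
            predict_enzymes(g, "l1")

    def test_similarities_all_at_least_threshold_and_permutation(self):
        edges = [
            SimilarityEdge("p1", "l1", 0.72),
            SimilarityEdge("p1", "l2", 0.66),
            SimilarityEdge("p1", "l3", 0.91),
        ]
        enzymes = [enzyme("e1", "l1"), enzyme("e2", "l2"), enzyme("e3", "l3")]
        g = build_tripartite(edges, enzymes, GenomeAnnotation())
        preds = predict_enzymes(g, "p1")
        assert sorted(p.enzyme_id for p in preds) == ["e1", "e2", "e3"]
        assert all(p.similarity >= 0.65 for p in preds)


class TestExport:
    @pytest.fixture
    def toy(self):
        return build_tripartite(
            [SimilarityEdge("p1", "l1", 0.8)], [enzyme("e1", "l1")], ANNOTATION
        )

    def test_graphml_round_trip_preserves_structure(self, tmp_path, toy):
        path = tmp_path / "g.graphml"
        export_graph(toy, path)
        back = import_graphml(path)
        assert nx.is_isomorphic(toy, back)
        assert back.nodes["e1"]["gene_counts"] == {"MAG1": 2, "MAG4": 0}
        assert back.edges["p1", "l1"]["weight"] == pytest.approx(0.8)
        check_tripartite(back)

    def test_edge_tsv_weight_only_on_similarity_rows(self, tmp_path, toy):
        base = tmp_path / "g"
        export_graph(toy, base, format="edge_tsv")
        rows = (tmp_path / "g.edges.tsv").read_text().splitlines()[1:]
        by_type = {r.split("\t")[2]: r.split("\t")[3] for r in rows}
        assert by_type["similarity"] == "0.8000"
        assert by_type["catalysis"] == ""

    def test_empty_graph_exports_headers_only(self, tmp_path):
        g = nx.Graph()
        export_graph(g, tmp_path / "e", format="edge_tsv")
        assert (tmp_path / "e.nodes.tsv").read_text().startswith("id\t")
        assert len((tmp_path / "e.edges.tsv").read_text().splitlines()) == 1
        export_graph(g, tmp_path / "e.graphml")
        assert import_graphml(tmp_path / "e.graphml").number_of_nodes() == 0

    def test_summary_counts(self, toy):
        text = summarize_graph(toy, classify_cases(toy))
        assert "PDCC nodes: 1" in text
        assert "similarity edges: 1" in text
        assert "case_i: 1" in text
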