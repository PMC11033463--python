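import numpy as np
import pytest

from acukg.kg import KnowledgeGraph, build_graph, kg_stats, one_hop_query
from acukg.schema import EntityType, RelationType, Triple
from acukg.trie import DomainDictionary


def t(head, rel, tail):
    r = RelationType(rel)
    return Triple(head, r.head_type, r, tail, r.tail_type)


@pytest.fixture
def cad_graph():
    """Toy graph mirroring a coronary-artery-disease neighborhood."""
    kg = KnowledgeGraph()
    kg.add_entity("coronary artery disease", EntityType.DIS)
    for s in ["shortness of breath", "sweating"]:
        kg.add_entity(s, EntityType.SYM)
        kg.add_triple(t("coronary artery disease", "DIS-SYM", s))
    for o in ["pointing", "pressing", "kneading"]:
        kg.add_entity(o, EntityType.OPE)
        kg.add_triple(t("coronary artery disease", "DIS-OPE", o))
    for x in ["Zhimen", "Zhiyang"]:
        kg.add_entity(x, EntityType.XW)
        kg.add_triple(t("coronary artery disease", "DIS-XW", x))
    return kg


class TestOneHop:
    def test_disease_neighborhood_grouped_by_relation(self, cad_graph):
        res = cad_graph.one_hop("coronary artery disease")
        assert res["found"] and res["etype"] == "DIS"
        assert res["relations"]["DIS-SYM"] == ["shortness of breath", "sweating"]
        assert res["relations"]["DIS-OPE"] == ["kneading", "pointing", "pressing"]
        assert res["relations"]["DIS-XW"] == ["Zhimen", "Zhiyang"]

    def test_incoming_edges_count_as_neighbors(self, cad_graph):
        res = cad_graph.one_hop("Zhimen")
        assert res["relations"] == {"DIS-XW": ["coronary artery disease"]}

    def test_unknown_entity_not_found(self, cad_graph):
        res = one_hop_query(cad_graph, "nonexistent")
        assert res == {"found": False, "entity": "nonexistent", "etype": None, "relations": {}}

    def test_repeated_queries_identical(self, cad_graph):
        assert cad_graph.one_hop("sweating") == cad_graph.one_hop("sweating")

    def test_matches_adjacency_oracle_on_random_graph(self):
        rng = np.random.default_rng(13)
        kg = KnowledgeGraph()
        dis = [f"病{i}" for i in range(10)]
        sym = [f"症{i}" for i in range(10)]
        for d in dis:
            kg.add_entity(d, EntityType.DIS)
        for s in sym:
            kg.add_entity(s, EntityType.SYM)
        adjacency: dict[str, set[str]] = {n: set() for n in dis + sym}
        for _ in range(60):
            d, s = rng.choice(dis), rng.choice(sym)
            kg.add_triple(t(d, "DIS-SYM", s))
            adjacency[d].add(s)
            adjacency[s].add(d)
        for n in dis + sym:
            res = kg.one_hop(n)
            got = {x for xs in res["relations"].values() for x in xs}
            assert got == adjacency[n]


class TestBuildGraph:
    def test_dictionary_entities_filtered_by_corpus_occurrence(self):
        d = DomainDictionary.from_entries(
            [(f"词{i}", EntityType.DIS) for i in range(10)]
        )
        corpus = [("词0", EntityType.DIS, "trie"), ("词3", EntityType.DIS, "trie")]
        kg = build_graph(d, corpus)
        assert set(kg.nodes) == {"词0", "词3"}
        assert kg.excluded_dictionary_entries == 8

    def test_kb_entities_included_without_corpus_mentions(self):
        kg = build_graph(None, [], kb_triples=[t("鼻炎", "DIS-SYM", "流涕")])
        assert set(kg.nodes) == {"鼻炎", "流涕"}
        assert len(kg.triples()) == 1

    def test_triple_with_filtered_endpoint_dropped_and_counted(self):
        kg = build_graph(None, [("推拿", EntityType.OPE, "trie")],
                         rule_triples=[t("推拿", "OPE-XW", "曲池")])
        assert kg.triples() == []
        assert kg.dropped_triples == 1

    def test_node_set_equals_set_algebra_oracle(self, small_fixture):
        dictionary, docs, ledger = small_fixture
        corpus_entities = [
            (sp.surface, sp.etype, "trie") for _, sp in
            ((i, s) for doc in docs for i, s in ledger.spans[doc.doc_id])
        ] + [
            (sp.surface, sp.etype, "trie")
            for doc in docs
            for sp in ledger.title_spans[doc.doc_id]
        ]
        kb = [t("鼻炎", "DIS-SYM", "流涕")]
        kg = build_graph(dictionary, corpus_entities, kb_triples=kb)
        want = set(ledger.nodes) | {"鼻炎", "流涕"}
        assert set(kg.nodes) == want

    def test_occurrence_counts_accumulate(self):
        kg = build_graph(None, [("推拿", EntityType.OPE, "trie")] * 3)
        assert kg.nodes["推拿"]["occurrences"] == 3

    def test_retyping_a_surface_rejected(self):
        kg = KnowledgeGraph()
        kg.add_entity("头痛", EntityType.SYM)
        with pytest.raises(ValueError, match="typed"):
            kg.add_entity("头痛", EntityType.DIS)

    def test_self_loops_dropped(self):
        kg = KnowledgeGraph()
        kg.add_entity("推拿", EntityType.OPE)
        assert not kg.add_triple(t("推拿", "OPE-XW", "推拿"))


class TestStatsAndExport:
    def test_empty_graph_all_zero(self):
        stats = kg_stats(KnowledgeGraph())
        assert stats["entity_total"] == 0 and stats["relation_total"] == 0
        assert all(v == 0 for v in stats["entity_counts"].values())

    def test_counts_match_generator_ledger(self, small_fixture, tmp_path):
        from acukg.pipeline import run_pipeline

        dictionary, docs, ledger = small_fixture
        kg = run_pipeline(docs, dictionary).graph
        stats = kg.stats()
        want_entities: dict[str, int] = {}
        for etype in ledger.nodes.values():
            want_entities[etype.value] = want_entities.get(etype.value, 0) + 1
        for code, count in want_entities.items():
            assert stats["entity_counts"][code] == count
        assert stats["entity_total"] == sum(stats["entity_counts"].values())
        assert stats["relation_total"] == sum(stats["relation_counts"].values())
        assert stats["relation_total"] == len(ledger.graph_triples)

    def test_csv_round_trip_lossless(self, cad_graph, tmp_path):
        cad_graph.export(tmp_path / "kg", "csv")
        back = KnowledgeGraph.from_csv(tmp_path / "kg")
        assert set(back.nodes) == set(cad_graph.nodes)
        assert {x.key() for x in back.triples()} == {x.key() for x in cad_graph.triples()}
        assert all(
            back.nodes[n]["etype"] == cad_graph.nodes[n]["etype"] for n in back.nodes
        )

    def test_graphml_round_trip_preserves_structure(self, cad_graph, tmp_path):
        import networkx as nx

        path = tmp_path / "kg.graphml"
        cad_graph.export(path, "graphml")
        g = nx.read_graphml(path)
        assert set(g.nodes) == set(cad_graph.nodes)
        assert g.number_of_edges() == len(cad_graph.triples())

    def test_cypher_statement_counts(self, cad_graph, tmp_path):
        path = tmp_path / "kg.cypher"
        cad_graph.export(path, "cypher")
        lines = path.read_text(encoding="utf-8").splitlines()
        merges = [l for l in lines if l.startswith("MERGE")]
        matches = [l for l in lines if l.startswith("MATCH")]
        assert len(merges) == len(cad_graph.nodes)
        assert len(matches) == len(cad_graph.triples())

    def test_empty_graph_exports_are_valid(self, tmp_path):
        kg = KnowledgeGraph()
        kg.export(tmp_path / "kg", "csv")
        assert (tmp_path / "kg" / "nodes.csv").exists()
        back = KnowledgeGraph.from_csv(tmp_path / "kg")
        assert back.graph.number_of_nodes() == 0
        kg.export(tmp_path / "e.cypher", "cypher")
        assert (tmp_path / "e.cypher").read_text(encoding="utf-8") == ""

    def test_unknown_format_rejected(self, cad_graph, tmp_path):
        with pytest.raises(ValueError, match="format"):
            cad_graph.export(tmp_path / "x", "parquet")
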