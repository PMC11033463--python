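import numpy as np
import pytest

from acukg.bio import EntitySpan
from acukg.relations import (
    RuleConfig,
    classify_document,
    extract_keyword_relations,
    extract_proximity_relations,
    extract_relations,
    extract_subject_relations,
)
from acukg.schema import EntityType, RelationType


def span(surface, etype, start=0):
    return EntitySpan(start, start + len(surface), surface, EntityType(etype), "fused")


class TestClassifyDocument:
    def test_disease_title_is_disease_therapy(self):
        cls, subject = classify_document([span("偏头痛", "DIS")])
        assert cls == "disease_therapy" and subject.surface == "偏头痛"

    def test_therapy_only_title_is_therapy_intro(self):
        cls, subject = classify_document([span("推拿", "OPE")])
        assert cls == "therapy_intro" and subject.surface == "推拿"

    def test_disease_takes_precedence_over_therapy(self):
        cls, subject = classify_document([span("推拿", "OPE"), span("偏头痛", "DIS", 5)])
        assert cls == "disease_therapy" and subject.etype == EntityType.DIS

    def test_no_entities_is_other(self):
        assert classify_document([]) == ("other", None)


class TestSubjectRule:
    def test_body_symptom_links_to_subject_disease(self):
        subject = span("偏头痛", "DIS")
        triples = extract_subject_relations(
            "disease_therapy", subject, [(0, span("头痛", "SYM"))], "d1"
        )
        assert len(triples) == 1
        t = triples[0]
        assert (t.head, t.relation, t.tail) == ("偏头痛", RelationType.DIS_SYM, "头痛")

    def test_no_body_entities_yields_nothing(self):
        assert extract_subject_relations("disease_therapy", span("感冒", "DIS"), []) == []

    def test_therapy_intro_disease_fills_head_endpoint(self):
        subject = span("艾灸", "OPE")
        triples = extract_subject_relations(
            "therapy_intro", subject, [(1, span("感冒", "DIS"))], "d1"
        )
        assert [(t.head, t.relation.value, t.tail) for t in triples] == [
            ("感冒", "DIS-OPE", "艾灸")
        ]

    def test_unknown_class_raises(self):
        with pytest.raises(ValueError):
            extract_subject_relations("other", span("x", "DIS"), [])

    def test_matches_allowed_type_table_oracle(self):
        rng = np.random.default_rng(11)
        types = ["DIS", "SYM", "XW", "OPE", "FUN"]
        allowed = {
            "disease_therapy": {"SYM": "DIS-SYM", "OPE": "DIS-OPE", "XW": "DIS-XW"},
            "therapy_intro": {"XW": "OPE-XW", "FUN": "OPE-FUN", "DIS": "DIS-OPE"},
        }
        for doc_class, subject_type in [("disease_therapy", "DIS"), ("therapy_intro", "OPE")]:
            subject = span("主体词", subject_type)
            entities = [
                (int(rng.integers(0, 5)), span(f"实体{i}", rng.choice(types)))
                for i in range(30)
            ]
            got = {
                (t.head, t.relation.value, t.tail)
                for t in extract_subject_relations(doc_class, subject, entities, "d")
            }
            want = set()
            for _, sp in entities:
                rel = allowed[doc_class].get(sp.etype.value)
                if rel is None:
                    continue
                if rel.startswith(sp.etype.value):
                    want.add((sp.surface, rel, subject.surface))
                else:
                    want.add((subject.surface, rel, sp.surface))
            assert got == want


class TestProximityRule:
    def test_therapy_with_two_acupoints_in_sentence(self):
        sents = ["体针推拿配穴操作：曲池、合谷"]
        ents = [
            (0, span("体针推拿", "OPE")),
            (0, span("曲池", "XW", 9)),
            (0, span("合谷", "XW", 12)),
        ]
        triples = extract_proximity_relations(sents, ents)
        assert {(t.head, t.tail) for t in triples} == {("体针推拿", "曲池"), ("体针推拿", "合谷")}
        assert all(t.relation == RelationType.OPE_XW for t in triples)

    def test_acupoints_alone_yield_nothing(self):
        assert extract_proximity_relations(["曲池合谷"], [(0, span("曲池", "XW"))]) == []

    def test_cross_sentence_pairs_excluded_by_default(self):
        ents = [(0, span("推拿", "OPE")), (1, span("曲池", "XW"))]
        assert extract_proximity_relations(["推拿。", "曲池。"], ents) == []

    def test_character_window_spans_sentences(self):
        ents = [(0, span("推拿", "OPE", 0)), (1, span("曲池", "XW", 0))]
        triples = extract_proximity_relations(["推拿。", "曲池。"], ents, window=10)
        assert len(triples) == 1

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            n_sent = int(rng.integers(1, 5))
            sents = ["句" * 10 for _ in range(n_sent)]
            ents = [
                (int(rng.integers(0, n_sent)), span(f"e{i}", rng.choice(["OPE", "XW", "SYM"])))
                for i in range(int(rng.integers(0, 10)))
            ]
            got = {(t.head, t.tail) for t in extract_proximity_relations(sents, ents)}
            want = {
                (o.surface, x.surface)
                for oi, o in ents
                if o.etype == EntityType.OPE
                for xi, x in ents
                if x.etype == EntityType.XW and oi == xi
            }
            assert got == want


class TestKeywordRule:
    def test_efficacy_sentence_links_therapy_and_function(self):
        sents = ["按揉太阳穴，功效：止血。"]
        ents = [(0, span("按揉", "OPE")), (0, span("止血", "FUN", 10))]
        triples = extract_keyword_relations(sents, ents)
        assert [(t.head, t.relation.value, t.tail) for t in triples] == [
            ("按揉", "OPE-FUN", "止血")
        ]

    def test_keyword_without_function_entity_yields_nothing(self):
        assert extract_keyword_relations(["功效很好。"], [(0, span("按揉", "OPE"))]) == []

    def test_function_without_keyword_yields_nothing(self):
        ents = [(0, span("按揉", "OPE")), (0, span("止血", "FUN", 5))]
        assert extract_keyword_relations(["按揉可以止血。"], ents) == []

    def test_acupoint_function_pair(self):
        sents = ["曲池功能清热。"]
        ents = [(0, span("曲池", "XW")), (0, span("清热", "FUN", 4))]
        triples = extract_keyword_relations(sents, ents)
        assert [(t.relation.value) for t in triples] == ["XW-FUN"]


class TestDocumentLevel:
    def test_union_of_rules_deduplicated(self, small_fixture):
        dictionary, docs, ledger = small_fixture
        for doc in docs:
            sentences = ledger.sentences[doc.doc_id]
            entities = ledger.spans[doc.doc_id]
            doc_class, triples = extract_relations(
                doc.doc_id, ledger.title_spans[doc.doc_id], sentences, entities
            )
            assert doc_class == ledger.doc_class[doc.doc_id]
            keys = [t.key() for t in triples]
            assert len(keys) == len(set(keys))
            # document output equals the union of the three rule families
            subj = extract_subject_relations(
                doc_class, ledger.title_spans[doc.doc_id][0], entities, doc.doc_id
            )
            prox = extract_proximity_relations(sentences, entities, None, doc.doc_id)
            kw = extract_keyword_relations(sentences, entities, None, doc.doc_id)
            assert set(keys) == {t.key() for t in subj + prox + kw}

    def test_entity_order_invariance(self, small_fixture):
        dictionary, docs, ledger = small_fixture
        doc = docs[0]
        sentences = ledger.sentences[doc.doc_id]
        entities = ledger.spans[doc.doc_id]
        _, a = extract_relations(doc.doc_id, ledger.title_spans[doc.doc_id], sentences, entities)
        _, b = extract_relations(
            doc.doc_id, ledger.title_spans[doc.doc_id], sentences, entities[::-1]
        )
        assert {t.key() for t in a} == {t.key() for t in b}

    def test_signatures_always_valid(self, small_fixture):
        dictionary, docs, ledger = small_fixture
        for doc in docs:
            _, triples = extract_relations(
                doc.doc_id,
                ledger.title_spans[doc.doc_id],
                ledger.sentences[doc.doc_id],
                ledger.spans[doc.doc_id],
            )
            for t in triples:
                assert (t.head_type, t.tail_type) == (
                    t.relation.head_type,
                    t.relation.tail_type,
                )


def test_rule_config_yaml_round_trip(tmp_path):
    p = tmp_path / "rules.yaml"
    p.write_text(
        "proximity_window: 25\nfunction_keywords: [功效]\n"
        "doc_class_rules:\n  disease_therapy: [DIS-SYM]\n",
        encoding="utf-8",
    )
    cfg = RuleConfig.from_yaml(p)
    assert cfg.proximity_window == 25
    assert cfg.function_keywords == ["功效"]
    assert cfg.doc_class_rules["disease_therapy"] == [RelationType.DIS_SYM]
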