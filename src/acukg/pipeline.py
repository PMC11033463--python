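"""End-to-end orchestration: documents -> NER -> fusion -> relations -> graph.

Ties the stages together the way the batch CLI runs them.  The model stage
is pluggable: pass a fitted :class:`~acukg.templatefc.TemplateFCTagger`, any
callable mapping sentences to tag sequences, or nothing (dictionary-only
run, in which the fusion step degenerates to the trie tags).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

from .bio import EntitySpan, tags_to_spans
from .corpus import Document, clean_text, split_sentences
from .fusion import FusionRecord, fuse_sequence
from .kg import KnowledgeGraph, build_graph
from .relations import RuleConfig, extract_relations
from .schema import EntityType, Triple
from .trie import DomainDictionary, bio_annotate

TagsFn = Callable[[Sequence[str]], list[list[str]]]


@dataclass
class PipelineResult:
    graph: KnowledgeGraph
    doc_classes: dict[str, str] = field(default_factory=dict)
    triples: list[Triple] = field(default_factory=list)
    conflicts: list[tuple[str, FusionRecord]] = field(default_factory=list)


def run_pipeline(
    docs: Sequence[Document],
    dictionary: DomainDictionary,
    model_tags_fn: TagsFn | None = None,
    config: RuleConfig | None = None,
    clean: bool = False,
) -> PipelineResult:
    """Run NER + fusion + relation rules over documents and assemble the graph."""
    config = config or RuleConfig()
    corpus_entities: list[tuple[str, EntityType, str]] = []
    all_triples: list[Triple] = []
    result = PipelineResult(graph=KnowledgeGraph())

    for doc in docs:
        title = clean_text(doc.title) if clean else doc.title
        body = clean_text(doc.body) if clean else doc.body
        sentences = split_sentences(body)

        title_spans = dictionary.find_spans(title)
        trie_tags = [bio_annotate(s, dictionary) for s in sentences]
        if model_tags_fn is not None:
            model_tags = model_tags_fn(sentences)
            records: list[FusionRecord] = []
            fused_tags = []
            for t_seq, m_seq in zip(trie_tags, model_tags):
                recs: list[FusionRecord] = []
                fused_tags.append(fuse_sequence(t_seq, m_seq, recs))
                records.extend(recs)
            result.conflicts.extend(
                (doc.doc_id, r) for r in records if r.rule_fired == "conflict"
            )
        else:
            fused_tags = trie_tags

        entities: list[tuple[int, EntitySpan]] = []
        for i, (sent, tags) in enumerate(zip(sentences, fused_tags)):
            for sp in tags_to_spans(sent, tags, source="fused"):
                entities.append((i, sp))

        doc_class, triples = extract_relations(
            doc.doc_id, title_spans, sentences, entities, config
        )
        result.doc_classes[doc.doc_id] = doc_class
        all_triples.extend(triples)

        for sp in title_spans:
            corpus_entities.append((sp.surface, sp.etype, "trie"))
        for _, sp in entities:
            corpus_entities.append((sp.surface, sp.etype, sp.source))

    result.graph = build_graph(
        dictionary, corpus_entities, kb_entities=(), kb_triples=(), rule_triples=all_triples
    )
    result.triples = all_triples
    return result


def entity_f1(
    gold: Sequence[tuple[str, Sequence[str]]],
    predicted: Sequence[Sequence[str]],
) -> float:
    """Entity-level micro F1: a hit is an exact (start, end, type) span match."""
    tp = fp = fn = 0
    for (sent, gold_tags), pred_tags in zip(gold, predicted):
        g = {(s.start, s.end, s.etype) for s in tags_to_spans(sent, list(gold_tags))}
        p = {(s.start, s.end, s.etype) for s in tags_to_spans(sent, list(pred_tags))}
        tp += len(g & p)
        fp += len(p - g)
        fn += len(g - p)
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)
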