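"""Rule-based relation extraction.

Three rule families produce the six relation types:

* **Subject-word rules** — the document's title names its subject.  A title
  containing a disease entity marks disease-therapy literature, whose body
  entities attach to the subject disease (DIS-SYM, DIS-OPE, DIS-XW).  A
  title containing a therapy but no disease marks therapy-introduction
  literature, whose body acupoints and functions attach to the subject
  therapy (OPE-XW, OPE-FUN) and whose body diseases link to it (DIS-OPE).
* **Proximity rule** — a therapy and an acupoint mentioned together (same
  sentence by default, or within a character window) are related OPE-XW,
  reflecting the "technique: acupoint list" phrasing of treatment prose.
* **Keyword rules** — in sentences containing an efficacy keyword
  (功效/作用/功能), therapy-function and acupoint-function pairs are related
  (OPE-FUN, XW-FUN).

Duplicate triples across rules are merged; every firing keeps its provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .bio import EntitySpan
from .schema import EntityType, RelationType, Triple

DEFAULT_FUNCTION_KEYWORDS = ["功效", "作用", "功能"]

#: Relations each document class licenses for the subject rule.
DOC_CLASS_RULES: dict[str, list[RelationType]] = {
    "disease_therapy": [RelationType.DIS_SYM, RelationType.DIS_OPE, RelationType.DIS_XW],
    "therapy_intro": [RelationType.DIS_OPE, RelationType.OPE_XW, RelationType.OPE_FUN],
}


@dataclass
class RuleConfig:
    """Tunable knobs of the rule extractor."""

    doc_class_rules: dict[str, list[RelationType]] = field(
        default_factory=lambda: {k: list(v) for k, v in DOC_CLASS_RULES.items()}
    )
    proximity_window: int | None = None  # None = same sentence
    function_keywords: list[str] = field(default_factory=lambda: list(DEFAULT_FUNCTION_KEYWORDS))
    max_pairs_per_sentence: int = 1000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RuleConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        cfg = cls()
        if "proximity_window" in data:
            cfg.proximity_window = data["proximity_window"]
        if "function_keywords" in data:
            cfg.function_keywords = list(data["function_keywords"])
        if "max_pairs_per_sentence" in data:
            cfg.max_pairs_per_sentence = int(data["max_pairs_per_sentence"])
        if "doc_class_rules" in data:
            cfg.doc_class_rules = {
                klass: [RelationType(r) for r in rels]
                for klass, rels in data["doc_class_rules"].items()
            }
        return cfg


def classify_document(
    title_spans: Sequence[EntitySpan],
) -> tuple[str, EntitySpan | None]:
    """Classify by title content; returns (doc_class, subject span or None)."""
    dis = [s for s in title_spans if s.etype == EntityType.DIS]
    if dis:
        return "disease_therapy", dis[0]
    ope = [s for s in title_spans if s.etype == EntityType.OPE]
    if ope:
        return "therapy_intro", ope[0]
    return "other", None


def _make(
    head: tuple[str, EntityType],
    rel: RelationType,
    tail: tuple[str, EntityType],
    doc_id: str,
    sent_idx: int,
    rule: str,
) -> Triple:
    return Triple(head[0], head[1], rel, tail[0], tail[1], f"{doc_id}:{sent_idx}:{rule}")


def extract_subject_relations(
    doc_class: str,
    subject: EntitySpan,
    entities: Sequence[tuple[int, EntitySpan]],
    doc_id: str = "",
    config: RuleConfig | None = None,
) -> list[Triple]:
    """Link body entities to the title subject per the document-class table.

    ``entities`` are (sentence_index, span) pairs from the body.  The subject
    fills whichever endpoint of each licensed relation matches its type; the
    body entity fills the other.  Self-links and duplicates are dropped.
    """
    config = config or RuleConfig()
    allowed = config.doc_class_rules.get(doc_class)
    if allowed is None:
        raise ValueError(f"no subject rules for document class {doc_class!r}")
    out: dict[tuple, Triple] = {}
    for sent_idx, span in entities:
        for rel in allowed:
            if subject.etype == rel.head_type and span.etype == rel.tail_type:
                head, tail = (subject.surface, subject.etype), (span.surface, span.etype)
            elif subject.etype == rel.tail_type and span.etype == rel.head_type:
                head, tail = (span.surface, span.etype), (subject.surface, subject.etype)
            else:
                continue
            if head[0] == tail[0]:
                continue
            tri = _make(head, rel, tail, doc_id, sent_idx, "subject")
            out.setdefault(tri.key(), tri)
    return list(out.values())


def _sentence_offsets(sentences: Sequence[str]) -> list[int]:
    offs = [0]
    for s in sentences:
        offs.append(offs[-1] + len(s))
    return offs


def extract_proximity_relations(
    sentences: Sequence[str],
    entities: Sequence[tuple[int, EntitySpan]],
    window: int | None = None,
    doc_id: str = "",
) -> list[Triple]:
    """OPE-XW triples for therapy/acupoint pairs that co-occur closely.

    With ``window=None`` co-occurrence means the same sentence; with an
    integer window it means span starts within ``window`` characters in the
    whole document.
    """
    opes = [(i, s) for i, s in entities if s.etype == EntityType.OPE]
    xws = [(i, s) for i, s in entities if s.etype == EntityType.XW]
    out: dict[tuple, Triple] = {}
    offs = _sentence_offsets(sentences)
    for oi, osp in opes:
        for xi, xsp in xws:
            if window is None:
                if oi != xi:
                    continue
            else:
                if abs((offs[oi] + osp.start) - (offs[xi] + xsp.start)) > window:
                    continue
            tri = _make(
                (osp.surface, EntityType.OPE),
                RelationType.OPE_XW,
                (xsp.surface, EntityType.XW),
                doc_id,
                oi,
                "proximity",
            )
            out.setdefault(tri.key(), tri)
    return list(out.values())


def extract_keyword_relations(
    sentences: Sequence[str],
    entities: Sequence[tuple[int, EntitySpan]],
    keywords: Sequence[str] | None = None,
    doc_id: str = "",
) -> list[Triple]:
    """OPE-FUN and XW-FUN triples in sentences containing an efficacy keyword."""
    keywords = list(keywords) if keywords is not None else DEFAULT_FUNCTION_KEYWORDS
    out: dict[tuple, Triple] = {}
    for sent_idx, sent in enumerate(sentences):
        if not any(kw in sent for kw in keywords):
            continue
        here = [s for i, s in entities if i == sent_idx]
        funs = [s for s in here if s.etype == EntityType.FUN]
        if not funs:
            continue
        for fun in funs:
            for s in here:
                if s.etype == EntityType.OPE:
                    tri = _make(
                        (s.surface, EntityType.OPE), RelationType.OPE_FUN,
                        (fun.surface, EntityType.FUN), doc_id, sent_idx, "keyword",
                    )
                elif s.etype == EntityType.XW:
                    tri = _make(
                        (s.surface, EntityType.XW), RelationType.XW_FUN,
                        (fun.surface, EntityType.FUN), doc_id, sent_idx, "keyword",
                    )
                else:
                    continue
                out.setdefault(tri.key(), tri)
    return list(out.values())


def extract_relations(
    doc_id: str,
    title_spans: Sequence[EntitySpan],
    sentences: Sequence[str],
    entities: Sequence[tuple[int, EntitySpan]],
    config: RuleConfig | None = None,
) -> tuple[str, list[Triple]]:
    """Run all three rule families on one document and merge the outputs.

    Returns the document class and the deduplicated triple list (first-seen
    provenance kept).
    """
    config = config or RuleConfig()
    doc_class, subject = classify_document(title_spans)
    triples: dict[tuple, Triple] = {}

    def add(ts: Iterable[Triple]) -> None:
        for t in ts:
            triples.setdefault(t.key(), t)

    if doc_class != "other" and subject is not None:
        add(extract_subject_relations(doc_class, subject, entities, doc_id, config))
    add(extract_proximity_relations(sentences, entities, config.proximity_window, doc_id))
    add(extract_keyword_relations(sentences, entities, config.function_keywords, doc_id))
    return doc_class, list(triples.values())
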