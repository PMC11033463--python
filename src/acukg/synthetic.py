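"""Seeded synthetic fixtures: dictionaries, corpora with gold labels, gold graphs.

The generator emulates the kind of text the pipeline targets — short Chinese
treatment prose in which dictionary entities are embedded in recurring
sentence patterns — at a scale where every stage has an exactly known
answer.  Documents instantiate templates such as

* disease-therapy:  ``<DIS>的症状包括<SYM>、<SYM>。``  /  ``治疗<DIS>常用<OPE>，取<XW>、<XW>。``
* therapy-intro:    ``<OPE>操作：<XW>、<XW>。``  /  ``<XW>具有<FUN>功效。``

and the gold ledger records the exact spans, BIO tags, relation triples and
graph those templates imply, so pipeline output can be compared to ground
truth without any external data.

Entity surfaces are random strings over a fixed 500-character CJK inventory,
partitioned into a disjoint 100-character slice per entity type, and the
template scaffold characters are disjoint from all of them.  The partition
keeps the fixtures exactly recoverable (no substring of a sentence can
straddle an entity boundary or two types) and makes few-shot recovery a
well-posed learning problem at desk scale.  Real prose offers no such
guarantee — see the methods note for what that means for the tests.

Optional distractor noise inserts characters from a separate noise alphabet
at sentence starts only, so planted spans are never corrupted (their offsets
shift, which the ledger tracks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bio import EntitySpan, spans_to_tags
from .corpus import Document
from .schema import EntityType, RelationType, Triple
from .trie import DomainDictionary

#: Scaffold characters used by the templates; never used in entity surfaces.
SCAFFOLD_CHARS = set("的治疗症状包括常用取介绍操作其为具有功效功能主可配合按压于、。，：；！？")

_TYPE_ORDER = [EntityType.DIS, EntityType.SYM, EntityType.XW, EntityType.OPE, EntityType.FUN]


def _build_inventories() -> tuple[dict[EntityType, str], str]:
    """500 CJK chars split 100-per-type, plus a 50-char noise alphabet."""
    chars: list[str] = []
    code = 0x5500
    while len(chars) < 550:
        ch = chr(code)
        code += 1
        if ch in SCAFFOLD_CHARS:
            continue
        chars.append(ch)
    per_type = {t: "".join(chars[i * 100 : (i + 1) * 100]) for i, t in enumerate(_TYPE_ORDER)}
    return per_type, "".join(chars[500:550])


TYPE_INVENTORIES, NOISE_ALPHABET = _build_inventories()


@dataclass
class FixtureSpec:
    """Parameters of one synthetic study condition."""

    n_entities_per_type: int = 8
    entity_length_range: tuple[int, int] = (2, 5)
    n_documents: int = 12
    noise_rate: float = 0.0
    seed: int = 0


@dataclass
class GoldLedger:
    """Ground truth for one generated corpus."""

    title_spans: dict[str, list[EntitySpan]] = field(default_factory=dict)
    sentences: dict[str, list[str]] = field(default_factory=dict)
    spans: dict[str, list[tuple[int, EntitySpan]]] = field(default_factory=dict)
    tags: dict[str, list[list[str]]] = field(default_factory=dict)
    doc_class: dict[str, str] = field(default_factory=dict)
    triples: dict[str, list[Triple]] = field(default_factory=dict)
    #: Graph-level truth: every planted entity and every distinct triple.
    nodes: dict[str, EntityType] = field(default_factory=dict)
    graph_triples: dict[tuple, Triple] = field(default_factory=dict)

    def ner_examples(self) -> list[tuple[str, list[str]]]:
        """All (sentence, gold tags) pairs, title sentences excluded."""
        out = []
        for doc_id, sents in self.sentences.items():
            for sent, tags in zip(sents, self.tags[doc_id]):
                out.append((sent, tags))
        return out


def generate_dictionary(
    spec: FixtureSpec, extra_per_type: int = 0
) -> DomainDictionary:
    """Random typed surfaces, unique, deterministic per seed.

    ``extra_per_type`` adds distractor entries beyond what the corpus uses,
    exercising the isolated-node filter downstream.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.entity_length_range
    if not (1 <= lo <= hi <= 10):
        raise ValueError("entity_length_range must lie within (1, 10)")
    n = spec.n_entities_per_type + extra_per_type
    # crude feasibility guard: distinct surfaces available at the shortest length
    if n > 90 ** lo:
        raise ValueError("too many entities requested for the length range")
    d = DomainDictionary()
    for etype in _TYPE_ORDER:
        inventory = TYPE_INVENTORIES[etype]
        seen: set[str] = set()
        while len(seen) < n:
            length = int(rng.integers(lo, hi + 1))
            surface = "".join(rng.choice(list(inventory), size=length))
            if surface in seen:
                continue
            seen.add(surface)
            d.add(surface, etype)
    return d


class _SentenceBuilder:
    """Assemble a sentence from literal and entity parts, tracking offsets."""

    def __init__(self) -> None:
        self.parts: list[str] = []
        self.spans: list[EntitySpan] = []
        self.length = 0

    def lit(self, text: str) -> "_SentenceBuilder":
        self.parts.append(text)
        self.length += len(text)
        return self

    def ent(self, surface: str, etype: EntityType) -> "_SentenceBuilder":
        self.spans.append(
            EntitySpan(self.length, self.length + len(surface), surface, etype, "gold")
        )
        self.parts.append(surface)
        self.length += len(surface)
        return self

    def build(self) -> tuple[str, list[EntitySpan]]:
        return "".join(self.parts), self.spans


def _pick(rng: np.random.Generator, pool: list[str], k: int) -> list[str]:
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool[int(i)] for i in idx]


def generate_corpus(
    spec: FixtureSpec, dictionary: DomainDictionary
) -> tuple[list[Document], GoldLedger]:
    """Instantiate templated documents and their gold ledger.

    Documents alternate between the disease-therapy and therapy-introduction
    classes.  Only the first ``n_entities_per_type`` dictionary entries per
    type are planted; surplus entries stay corpus-absent distractors.
    """
    rng = np.random.default_rng(spec.seed + 1)
    pools: dict[EntityType, list[str]] = {t: [] for t in _TYPE_ORDER}
    for surface, etype in dictionary.entries.items():
        if len(pools[etype]) < spec.n_entities_per_type:
            pools[etype].append(surface)

    docs: list[Document] = []
    ledger = GoldLedger()

    for di in range(spec.n_documents):
        doc_id = f"doc{di:03d}"
        disease_doc = di % 2 == 0
        sentences: list[tuple[str, list[EntitySpan]]] = []
        triples: dict[tuple, Triple] = {}

        def add_triple(head, htype, rel, tail, ttype, sent_idx, rule):
            tri = Triple(head, htype, rel, tail, ttype, f"{doc_id}:{sent_idx}:{rule}")
            triples.setdefault(tri.key(), tri)

        if disease_doc:
            dis = _pick(rng, pools[EntityType.DIS], 1)[0]
            syms = _pick(rng, pools[EntityType.SYM], 2)
            ope = _pick(rng, pools[EntityType.OPE], 1)[0]
            xws = _pick(rng, pools[EntityType.XW], 2)
            fun = _pick(rng, pools[EntityType.FUN], 1)[0]

            title, title_spans = (
                _SentenceBuilder().ent(dis, EntityType.DIS).lit("的治疗").build()
            )
            b = _SentenceBuilder().ent(dis, EntityType.DIS).lit("的症状包括")
            b.ent(syms[0], EntityType.SYM).lit("、").ent(syms[1], EntityType.SYM).lit("。")
            sentences.append(b.build())
            b = _SentenceBuilder().lit("治疗").ent(dis, EntityType.DIS).lit("常用")
            b.ent(ope, EntityType.OPE).lit("，取")
            b.ent(xws[0], EntityType.XW).lit("、").ent(xws[1], EntityType.XW).lit("。")
            sentences.append(b.build())
            b = _SentenceBuilder().ent(ope, EntityType.OPE).lit("按压")
            b.ent(xws[0], EntityType.XW).lit("，功效：").ent(fun, EntityType.FUN).lit("。")
            sentences.append(b.build())

            # subject rule (title disease = subject)
            for s in syms:
                add_triple(dis, EntityType.DIS, RelationType.DIS_SYM, s, EntityType.SYM, 0, "subject")
            add_triple(dis, EntityType.DIS, RelationType.DIS_OPE, ope, EntityType.OPE, 1, "subject")
            for x in xws:
                add_triple(dis, EntityType.DIS, RelationType.DIS_XW, x, EntityType.XW, 1, "subject")
            # proximity rule: OPE with XW in sentences 1 and 2
            for x in xws:
                add_triple(ope, EntityType.OPE, RelationType.OPE_XW, x, EntityType.XW, 1, "proximity")
            # keyword rule in sentence 2 (功效)
            add_triple(ope, EntityType.OPE, RelationType.OPE_FUN, fun, EntityType.FUN, 2, "keyword")
            add_triple(xws[0], EntityType.XW, RelationType.XW_FUN, fun, EntityType.FUN, 2, "keyword")
            ledger.doc_class[doc_id] = "disease_therapy"
        else:
            ope = _pick(rng, pools[EntityType.OPE], 1)[0]
            xws = _pick(rng, pools[EntityType.XW], 2)
            funs = _pick(rng, pools[EntityType.FUN], 2)
            dis = _pick(rng, pools[EntityType.DIS], 1)[0]

            title, title_spans = (
                _SentenceBuilder().ent(ope, EntityType.OPE).lit("介绍").build()
            )
            b = _SentenceBuilder().ent(ope, EntityType.OPE).lit("操作：")
            b.ent(xws[0], EntityType.XW).lit("、").ent(xws[1], EntityType.XW).lit("。")
            sentences.append(b.build())
            b = _SentenceBuilder().ent(xws[0], EntityType.XW).lit("具有")
            b.ent(funs[0], EntityType.FUN).lit("功效。")
            sentences.append(b.build())
            b = _SentenceBuilder().ent(ope, EntityType.OPE).lit("可治")
            b.ent(dis, EntityType.DIS).lit("。")
            sentences.append(b.build())

            # subject rule (title therapy = subject)
            for x in xws:
                add_triple(ope, EntityType.OPE, RelationType.OPE_XW, x, EntityType.XW, 0, "subject")
            add_triple(ope, EntityType.OPE, RelationType.OPE_FUN, funs[0], EntityType.FUN, 1, "subject")
            add_triple(dis, EntityType.DIS, RelationType.DIS_OPE, ope, EntityType.OPE, 2, "subject")
            # proximity rule duplicates the OPE-XW pairs of sentence 0
            # keyword rule in sentence 1 (功效): XW-FUN
            add_triple(xws[0], EntityType.XW, RelationType.XW_FUN, funs[0], EntityType.FUN, 1, "keyword")
            ledger.doc_class[doc_id] = "therapy_intro"

        # optional distractor noise at sentence starts (never inside spans)
        final_sentences: list[tuple[str, list[EntitySpan]]] = []
        for sent, spans in sentences:
            if spec.noise_rate > 0 and rng.random() < spec.noise_rate:
                k = int(rng.integers(1, 4))
                prefix = "".join(rng.choice(list(NOISE_ALPHABET), size=k))
                sent = prefix + sent
                spans = [
                    EntitySpan(s.start + k, s.end + k, s.surface, s.etype, "gold")
                    for s in spans
                ]
            final_sentences.append((sent, spans))
        sentences = final_sentences

        body = "".join(s for s, _ in sentences)
        docs.append(Document(doc_id, title, body, source="synthetic"))
        ledger.title_spans[doc_id] = title_spans
        ledger.sentences[doc_id] = [s for s, _ in sentences]
        ledger.spans[doc_id] = [
            (i, sp) for i, (_, spans) in enumerate(sentences) for sp in spans
        ]
        ledger.tags[doc_id] = [
            spans_to_tags(len(sent), spans) for sent, spans in sentences
        ]
        ledger.triples[doc_id] = list(triples.values())

        for sp in title_spans:
            ledger.nodes.setdefault(sp.surface, sp.etype)
        for _, sp in ledger.spans[doc_id]:
            ledger.nodes.setdefault(sp.surface, sp.etype)
        for key, tri in triples.items():
            ledger.graph_triples.setdefault(key, tri)

    return docs, ledger


def generate_fixture(
    spec: FixtureSpec | None = None, extra_dictionary_entries: int = 2
) -> tuple[DomainDictionary, list[Document], GoldLedger]:
    """One-call fixture: dictionary (with distractors), corpus and ledger."""
    spec = spec or FixtureSpec()
    dictionary = generate_dictionary(spec, extra_per_type=extra_dictionary_entries)
    docs, ledger = generate_corpus(spec, dictionary)
    return dictionary, docs, ledger


def few_shot_episode(
    ledger: GoldLedger, n_train: int = 10, seed: int = 0
) -> tuple[list[tuple[str, list[str]]], list[tuple[str, list[str]]]]:
    """Sample ``n_train`` training sentences; the rest are held out."""
    examples = ledger.ner_examples()
    if n_train >= len(examples):
        raise ValueError("not enough sentences to hold any out")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(examples))
    train = [examples[int(i)] for i in order[:n_train]]
    test = [examples[int(i)] for i in order[n_train:]]
    return train, test


def few_shot_episode_per_type(
    ledger: GoldLedger, per_type: int = 10, seed: int = 0
) -> tuple[list[tuple[str, list[str]]], list[tuple[str, list[str]]]]:
    """Few-shot split with at least ``per_type`` training sentences per entity type.

    Shuffled sentences are taken into the training set until every entity
    type occurs in at least ``per_type`` of them; the rest are held out.
    """
    examples = ledger.ner_examples()
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(examples))
    counts = {t: 0 for t in _TYPE_ORDER}

    def types_in(tags: list[str]) -> set[EntityType]:
        return {EntityType(t[2:]) for t in tags if t != "O"}

    train: list[tuple[str, list[str]]] = []
    test: list[tuple[str, list[str]]] = []
    for i in order:
        ex = examples[int(i)]
        present = types_in(ex[1])
        if any(counts[t] < per_type for t in present):
            train.append(ex)
            for t in present:
                counts[t] += 1
        else:
            test.append(ex)
    if any(c < per_type for c in counts.values()) or not test:
        raise ValueError(
            f"corpus too small for {per_type} training sentences per type with a held-out set"
        )
    return train, test
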