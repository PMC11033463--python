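"""Trie-based dictionary entity extraction.

Each entity type has its own prefix tree (trie): a dictionary word is a
root-to-flag path, and words sharing a prefix share the prefix's path.  A
sentence is scanned left to right; at each position candidate substrings are
tried from the maximum entity length (10 characters) down to 1, the longest
dictionary match is emitted, and the scan resumes after it.  This yields
non-overlapping, greedy-longest matches and never re-emits entities nested
inside an already-matched entity.

Cross-type arbitration (the five tries are independent): the longest span
wins; equal-length competing spans are resolved by a fixed type priority
DIS > SYM > XW > OPE > FUN, following corpus frequency order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from sklearn.base import BaseEstimator

from .bio import EntitySpan, spans_to_tags
from .schema import EntityType

MAX_ENTITY_LEN = 10

#: Cross-type tie-break priority (most frequent type first).
TYPE_PRIORITY: list[EntityType] = [
    EntityType.DIS,
    EntityType.SYM,
    EntityType.XW,
    EntityType.OPE,
    EntityType.FUN,
]
_PRIORITY_RANK = {t: i for i, t in enumerate(TYPE_PRIORITY)}


class TrieNode:
    """A trie node: child map plus an end-of-word flag."""

    __slots__ = ("children", "is_end")

    def __init__(self) -> None:
        self.children: dict[str, TrieNode] = {}
        self.is_end = False


def add_trie_node(root: TrieNode, word: str) -> TrieNode:
    """Insert ``word`` as a root-to-flag path; the flag marks only the last node."""
    if not word or len(word) > MAX_ENTITY_LEN:
        warnings.warn(
            f"rejecting dictionary word {word!r}: length must be 1-{MAX_ENTITY_LEN}",
            stacklevel=2,
        )
        return root
    cur = root
    for ch in word:
        if ch not in cur.children:
            cur.children[ch] = TrieNode()
        cur = cur.children[ch]
    cur.is_end = True
    return root


def search_word(root: TrieNode, word: str, counter: list[int] | None = None) -> bool:
    """Exact membership test; ``counter`` (if given) accumulates node visits."""
    cur = root
    for ch in word:
        if counter is not None:
            counter[0] += 1
        nxt = cur.children.get(ch)
        if nxt is None:
            return False
        cur = nxt
    return cur.is_end


def find_entities(
    root: TrieNode, sentence: str, max_len: int = MAX_ENTITY_LEN
) -> list[tuple[int, str]]:
    """Greedy longest-match scan; returns ``(start, word)`` pairs in order.

    At each index the candidate lengths are tried longest-first; the first
    match wins, and scanning resumes immediately after it, so output spans
    never overlap.
    """
    entities: list[tuple[int, str]] = []
    index = 0
    n = len(sentence)
    while index < n:
        matched = False
        for j in range(min(max_len, n - index), 0, -1):
            word = sentence[index : index + j]
            if search_word(root, word):
                entities.append((index, word))
                index += j
                matched = True
                break
        if not matched:
            index += 1
    return entities


@dataclass
class DomainDictionary:
    """Typed surface-form dictionary backed by one trie per entity type."""

    entries: dict[str, EntityType] = field(default_factory=dict)
    tries: dict[EntityType, TrieNode] = field(
        default_factory=lambda: {t: TrieNode() for t in EntityType}
    )

    @classmethod
    def from_entries(cls, entries: Mapping[str, EntityType] | Iterable[tuple[str, EntityType]]):
        d = cls()
        items = entries.items() if isinstance(entries, Mapping) else entries
        for surface, etype in items:
            d.add(surface, etype)
        return d

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DomainDictionary":
        """Load surface<TAB>type lines (type in DIS/SYM/XW/OPE/FUN)."""
        d = cls()
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            surface, code = line.split("\t")
            d.add(surface, EntityType(code))
        return d

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for surface, etype in self.entries.items():
                fh.write(f"{surface}\t{etype.value}\n")

    def add(self, surface: str, etype: EntityType) -> None:
        if not surface or len(surface) > MAX_ENTITY_LEN:
            warnings.warn(
                f"rejecting dictionary entry {surface!r}: length must be 1-{MAX_ENTITY_LEN}",
                stacklevel=2,
            )
            return
        prev = self.entries.get(surface)
        if prev is not None and prev != etype:
            raise ValueError(
                f"surface {surface!r} already registered as {prev.value}, cannot re-add as {etype.value}"
            )
        self.entries[surface] = etype
        add_trie_node(self.tries[EntityType(etype)], surface)

    def __len__(self) -> int:
        return len(self.entries)

    def find_spans(self, sentence: str, max_len: int = MAX_ENTITY_LEN) -> list[EntitySpan]:
        """Run all five tries and arbitrate overlaps (longest, then type priority)."""
        candidates: list[EntitySpan] = []
        for etype in TYPE_PRIORITY:
            for start, word in find_entities(self.tries[etype], sentence, max_len):
                candidates.append(EntitySpan(start, start + len(word), word, etype, "trie"))
        candidates.sort(
            key=lambda s: (-(s.end - s.start), _PRIORITY_RANK[s.etype], s.start)
        )
        occupied = [False] * len(sentence)
        chosen: list[EntitySpan] = []
        for sp in candidates:
            if any(occupied[sp.start : sp.end]):
                continue
            chosen.append(sp)
            for i in range(sp.start, sp.end):
                occupied[i] = True
        chosen.sort(key=lambda s: s.start)
        return chosen


def bio_annotate(sentence: str, dictionary: DomainDictionary) -> list[str]:
    """Dictionary-annotate one sentence: matched spans as B/I tags, the rest O."""
    spans = dictionary.find_spans(sentence)
    return spans_to_tags(len(sentence), spans)


class TrieTagger(BaseEstimator):
    """Dictionary NER as an estimator: fit on (surface, type) pairs, predict BIO tags.

    Parameters
    ----------
    max_len : int
        Maximum entity length in characters; longer dictionary entries are
        rejected with a warning.
    """

    def __init__(self, max_len: int = MAX_ENTITY_LEN):
        self.max_len = max_len

    def fit(self, X: Sequence[str], y: Sequence[EntityType | str]):
        """Build the per-type tries from surfaces ``X`` and their types ``y``."""
        if len(X) != len(y):
            raise ValueError("X and y must have equal length")
        self.dictionary_ = DomainDictionary.from_entries(
            (surface, EntityType(t)) for surface, t in zip(X, y)
        )
        return self

    def predict(self, X: Sequence[str]) -> list[list[str]]:
        """BIO tag sequences for each sentence in ``X``."""
        if not hasattr(self, "dictionary_"):
            raise RuntimeError("TrieTagger is not fitted")
        return [
            spans_to_tags(len(s), self.dictionary_.find_spans(s, self.max_len)) for s in X
        ]

    def predict_spans(self, X: Sequence[str]) -> list[list[EntitySpan]]:
        if not hasattr(self, "dictionary_"):
            raise RuntimeError("TrieTagger is not fitted")
        return [self.dictionary_.find_spans(s, self.max_len) for s in X]
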