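"""BIO tag alphabet, span<->tag conversion, repair, and CoNLL-style I/O.

Tags are per-character: ``O`` outside entities, ``B-t``/``I-t`` for the first
and following characters of an entity of type ``t``.  The fixed tag order
below (O first, then B/I pairs in schema type order) is used everywhere a tag
index is needed, e.g. as the CRF label indexing and for deterministic
tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .schema import EntityType

O_TAG = "O"

#: Canonical tag order: O, then B/I per entity type in schema order.
TAGS: list[str] = [O_TAG] + [
    f"{p}-{t.value}" for t in EntityType for p in ("B", "I")
]
TAG_INDEX: dict[str, int] = {t: i for i, t in enumerate(TAGS)}


def validate_tag(tag: str) -> str:
    if tag not in TAG_INDEX:
        raise ValueError(f"unknown BIO tag {tag!r}")
    return tag


@dataclass(frozen=True)
class EntitySpan:
    """A typed half-open character span ``[start, end)`` in one sentence."""

    start: int
    end: int
    surface: str
    etype: EntityType
    source: str = "trie"  # trie | model | fused | kb

    def __post_init__(self) -> None:
        if not (self.end > self.start):
            raise ValueError("span must be non-empty")
        if len(self.surface) != self.end - self.start:
            raise ValueError("surface length must equal span width")


def spans_to_tags(n: int, spans: Iterable[EntitySpan]) -> list[str]:
    """Render non-overlapping spans over an ``n``-character sentence as BIO tags."""
    tags = [O_TAG] * n
    for sp in spans:
        if sp.end > n:
            raise ValueError(f"span {sp} exceeds sentence length {n}")
        if any(t != O_TAG for t in tags[sp.start : sp.end]):
            raise ValueError(f"span {sp} overlaps a previously placed span")
        tags[sp.start] = f"B-{sp.etype.value}"
        for i in range(sp.start + 1, sp.end):
            tags[i] = f"I-{sp.etype.value}"
    return tags


def tags_to_spans(sentence: str, tags: Sequence[str], source: str = "model") -> list[EntitySpan]:
    """Extract entity spans from a (valid) BIO tag sequence.

    An ``I-t`` that does not continue a ``B-t``/``I-t`` run opens a new span
    (i.e. inputs are read as if repaired; run :func:`bio_repair` first when
    the distinction matters).
    """
    if len(sentence) != len(tags):
        raise ValueError("tags length must equal sentence length")
    spans: list[EntitySpan] = []
    start = None
    etype: EntityType | None = None
    for i, tag in enumerate(tags):
        validate_tag(tag)
        if tag == O_TAG:
            if start is not None:
                spans.append(EntitySpan(start, i, sentence[start:i], etype, source))
                start, etype = None, None
            continue
        prefix, code = tag.split("-", 1)
        t = EntityType(code)
        if prefix == "B" or etype != t:
            if start is not None:
                spans.append(EntitySpan(start, i, sentence[start:i], etype, source))
            start, etype = i, t
    if start is not None:
        spans.append(EntitySpan(start, len(tags), sentence[start:], etype, source))
    return spans


def bio_repair(tags: Sequence[str]) -> list[str]:
    """Make a tag sequence BIO-valid: orphan ``I-t`` becomes ``B-t``."""
    out: list[str] = []
    prev = O_TAG
    for tag in tags:
        validate_tag(tag)
        if tag.startswith("I-"):
            t = tag[2:]
            if not (prev == f"B-{t}" or prev == f"I-{t}"):
                tag = f"B-{t}"
        out.append(tag)
        prev = tag
    return out


def read_conll(path: str | Path) -> list[tuple[str, list[str]]]:
    """Read two-column char<TAB>tag sentences separated by blank lines."""
    sentences: list[tuple[str, list[str]]] = []
    chars: list[str] = []
    tags: list[str] = []
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    for line in lines + [""]:
        if not line.strip():
            if chars:
                sentences.append(("".join(chars), tags))
                chars, tags = [], []
            continue
        ch, tag = line.split("\t")
        chars.append(ch)
        tags.append(validate_tag(tag))
    return sentences


def write_conll(sentences: Iterable[tuple[str, Sequence[str]]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sent, tags in sentences:
            if len(sent) != len(tags):
                raise ValueError("tags length must equal sentence length")
            for ch, tag in zip(sent, tags):
                fh.write(f"{ch}\t{validate_tag(tag)}\n")
            fh.write("\n")
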