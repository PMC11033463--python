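"""Corpus handling: cleaning, sentence segmentation and block division.

Documents are plain title+body text.  Downstream sequence models take at most
512 positions, two of which are reserved for the sequence-boundary markers, so
documents are divided into blocks of at most 510 characters.  Division is
greedy and never splits a sentence; heading sentences are carried along as
context of the block that follows them so that section titles stay attached
to their section's text.

Tokenization is character-level throughout the pipeline (the natural unit for
Chinese text, and it avoids a word-segmenter dependency), so "token count"
always means character count.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

DEFAULT_BLOCK_LIMIT = 510

#: Characters stripped by default in addition to control characters.
DEFAULT_SPECIAL_SYMBOLS = "﻿​‎‏□■◆●★☆▲△*#§†‡"

#: Default heading detector: numbered headings like "1.2", "三、", "(2)".
DEFAULT_HEADING_PATTERN = r"^\s*(?:[0-9０-９]+[\.、．)）]|[一二三四五六七八九十]+[、\.．]|[（(][0-9０-９一二三四五六七八九十]+[)）])"


@dataclass
class Document:
    doc_id: str
    title: str
    body: str
    source: str = ""


@dataclass
class Block:
    """A ≤510-character run of whole sentences from one document.

    ``context`` carries the nearest preceding heading sentence(s), so a block
    taken from the middle of a section still knows its section title.
    """

    doc_id: str
    block_index: int
    sentences: list[str]
    context: list[str] = field(default_factory=list)

    @property
    def token_count(self) -> int:
        return sum(len(s) for s in self.sentences)

    @property
    def text(self) -> str:
        return "".join(self.sentences)


class OversizedSentenceError(ValueError):
    """A single sentence exceeds the block limit and cannot be packed."""


def clean_text(raw: str, special_symbols: str = DEFAULT_SPECIAL_SYMBOLS) -> str:
    """Remove control characters and special symbols; collapse whitespace runs.

    Idempotent: ``clean_text(clean_text(s)) == clean_text(s)``.
    """
    drop = set(special_symbols)
    out = []
    for ch in raw:
        if ch in drop:
            continue
        # control/format chars go, but whitespace is left for the collapse below
        if unicodedata.category(ch).startswith("C") and not ch.isspace():
            continue
        out.append(ch)
    return re.sub(r"\s+", " ", "".join(out)).strip()


_SENT_DELIMS = "。！？；!?;\n"


def split_sentences(text: str) -> list[str]:
    """Split on sentence-final punctuation, keeping the delimiter with its sentence.

    Newlines also terminate sentences but are dropped from the output; apart
    from dropped newlines, concatenating the result reconstructs the input.
    """
    sentences: list[str] = []
    buf: list[str] = []
    for ch in text:
        if ch == "\n":
            if buf:
                sentences.append("".join(buf))
                buf = []
            continue
        buf.append(ch)
        if ch in _SENT_DELIMS:
            sentences.append("".join(buf))
            buf = []
    if buf:
        sentences.append("".join(buf))
    return sentences


def is_heading(sentence: str, pattern: str = DEFAULT_HEADING_PATTERN) -> bool:
    return re.match(pattern, sentence) is not None


def divide_blocks(
    doc: Document,
    limit: int = DEFAULT_BLOCK_LIMIT,
    heading_pattern: str = DEFAULT_HEADING_PATTERN,
) -> list[Block]:
    """Greedily pack the document's sentences into blocks of at most ``limit`` chars.

    Sentences are appended in order while the running block stays within the
    limit; a sentence that would overflow starts the next block.  Heading
    sentences are packed like any other sentence and additionally recorded as
    context of every subsequent block until the next heading.
    """
    sentences = split_sentences(doc.body)
    blocks: list[Block] = []
    current: list[str] = []
    current_len = 0
    current_heading: list[str] = []
    pending_heading: list[str] = []

    def flush() -> None:
        nonlocal current, current_len
        if current:
            blocks.append(
                Block(doc.doc_id, len(blocks), current, context=list(current_heading))
            )
            current = []
            current_len = 0

    for offset, sent in enumerate(sentences):
        if len(sent) > limit:
            raise OversizedSentenceError(
                f"document {doc.doc_id!r}: sentence #{offset} has {len(sent)} "
                f"characters, exceeding the block limit of {limit}"
            )
        if current_len + len(sent) > limit:
            flush()
        if not current:
            current_heading = pending_heading
        if is_heading(sent, heading_pattern):
            pending_heading = [sent]
        current.append(sent)
        current_len += len(sent)
    flush()
    return blocks


def read_corpus_jsonl(path: str | Path) -> list[Document]:
    """Read documents from JSONL with keys doc_id, title, body, source."""
    docs = []
    seen: set[str] = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        obj = json.loads(line)
        if obj["doc_id"] in seen:
            raise ValueError(f"duplicate doc_id {obj['doc_id']!r} in corpus")
        seen.add(obj["doc_id"])
        docs.append(
            Document(obj["doc_id"], obj.get("title", ""), obj.get("body", ""), obj.get("source", ""))
        )
    return docs


def write_corpus_jsonl(docs: Iterable[Document], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            fh.write(
                json.dumps(
                    {"doc_id": d.doc_id, "title": d.title, "body": d.body, "source": d.source},
                    ensure_ascii=False,
                )
                + "\n"
            )


def write_blocks_jsonl(blocks: Iterable[Block], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for b in blocks:
            fh.write(
                json.dumps(
                    {
                        "doc_id": b.doc_id,
                        "block_index": b.block_index,
                        "sentences": b.sentences,
                        "context": b.context,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )
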