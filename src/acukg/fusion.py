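"""Fusion of dictionary-based and model-based tag sequences.

The dictionary pass mines known entities with high precision; the model pass
mines potential entities the dictionary misses.  Fusion is per position:

* equal tags are kept as-is;
* a model entity tag overrides a dictionary ``O`` (the model found something
  new);
* a dictionary entity tag overrides a model ``O`` (curated knowledge is
  trusted);
* two different non-O tags are a genuine conflict: the dictionary tag wins
  and the position is logged, since the dictionary is curated domain
  knowledge while the model's type judgment on a contested span is the less
  reliable signal.

After per-position fusion the sequence is BIO-repaired (orphan ``I-t``
becomes ``B-t``) so the output is always a valid tagging.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .bio import O_TAG, bio_repair, validate_tag


@dataclass(frozen=True)
class FusionRecord:
    """One fused position: inputs, output and which rule fired."""

    position: int
    trie_tag: str
    model_tag: str
    fused_tag: str
    rule_fired: str  # agree | model_wins | trie_wins | conflict


def fuse_tag(trie_tag: str, model_tag: str) -> tuple[str, str]:
    """Fuse one position's tags; returns (fused_tag, rule_fired)."""
    validate_tag(trie_tag)
    validate_tag(model_tag)
    if trie_tag == model_tag:
        return trie_tag, "agree"
    if trie_tag == O_TAG:
        return model_tag, "model_wins"
    if model_tag == O_TAG:
        return trie_tag, "trie_wins"
    return trie_tag, "conflict"


def fuse_sequence(
    trie_seq: Sequence[str],
    model_seq: Sequence[str],
    records: list[FusionRecord] | None = None,
) -> list[str]:
    """Per-position fusion followed by BIO repair.

    ``records``, if given, collects one :class:`FusionRecord` per position
    (with the pre-repair fused tag) for conflict logging.
    """
    if len(trie_seq) != len(model_seq):
        raise ValueError(
            f"sequence length mismatch: trie {len(trie_seq)} vs model {len(model_seq)}"
        )
    fused: list[str] = []
    for i, (t_tag, m_tag) in enumerate(zip(trie_seq, model_seq)):
        tag, rule = fuse_tag(t_tag, m_tag)
        fused.append(tag)
        if records is not None:
            records.append(FusionRecord(i, t_tag, m_tag, tag, rule))
    return bio_repair(fused)


def write_conflict_log(
    rows: Iterable[tuple[str, FusionRecord]], path: str | Path
) -> None:
    """Write (doc_id, record) conflicts as TSV: doc_id, position, trie_tag, model_tag."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["doc_id", "position", "trie_tag", "model_tag"])
        for doc_id, rec in rows:
            if rec.rule_fired == "conflict":
                writer.writerow([doc_id, rec.position, rec.trie_tag, rec.model_tag])
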