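"""Published statistics of the full-scale acupuncture/tuina corpus.

The pipeline was originally applied to a corpus of 3,236 crawled posts plus
OCR'd literature, with a 14,691/5,142/594/579/357-entry domain dictionary.
These reference counts summarize the entity and relation inventory reported
for that full-scale run.  They are data, not results of this package: the
source corpus is not redistributable, so desk-scale runs use the synthetic
fixture generator instead.  The counts are kept here so their internal
arithmetic (per-type counts summing to the published totals) can be checked
mechanically.
"""

from __future__ import annotations

#: Entities extracted per type in the full-scale run.
REFERENCE_ENTITY_COUNTS: dict[str, int] = {
    "DIS": 3671,
    "SYM": 3252,
    "XW": 1491,
    "OPE": 1330,
    "FUN": 602,
}

#: Published entity total for the full-scale run.
REFERENCE_ENTITY_TOTAL = 10346

#: Relations extracted per type in the full-scale run.
REFERENCE_RELATION_COUNTS: dict[str, int] = {
    "DIS-SYM": 5566,
    "DIS-OPE": 6705,
    "DIS-XW": 6412,
    "OPE-XW": 6808,
    "OPE-FUN": 6824,
    "XW-FUN": 8604,
}

#: Published relation total for the full-scale run.
REFERENCE_RELATION_TOTAL = 40919


def entity_count_sum() -> int:
    """Sum of the per-type entity counts (to compare with the published total)."""
    return sum(REFERENCE_ENTITY_COUNTS.values())


def relation_count_sum() -> int:
    """Sum of the per-type relation counts (to compare with the published total)."""
    return sum(REFERENCE_RELATION_COUNTS.values())
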