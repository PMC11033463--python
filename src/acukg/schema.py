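"""Entity/relation taxonomy of the acupuncture-tuina knowledge graph.

The schema distinguishes five entity types — diseases (DIS), symptoms (SYM),
acupoints/meridians (XW), therapies (OPE) and functions/effects (FUN) — and
six directed relation types between them.  Diseases and symptoms overlap in
ordinary clinical language ("headache" can be either); the schema resolves the
ambiguity with a scope rule: a candidate surface is a disease only if it
appears in an authoritative disease nomenclature (ICD-10 or the Chinese
clinical terminology standard GB/T 16751.1), otherwise it is a symptom.

Meridians and acupoints are deliberately a single type: acupoints lie on
meridians and the number of meridians is small, so a meridian is stored as an
attribute of its acupoints rather than as a separate node class.
"""

from __future__ import annotations

import csv
import re
import unicodedata
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence


class EntityType(str, Enum):
    """The five entity classes: disease, symptom, acupoint, therapy, function."""

    DIS = "DIS"
    SYM = "SYM"
    XW = "XW"
    OPE = "OPE"
    FUN = "FUN"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class RelationType(str, Enum):
    """The six relation classes, each with a fixed (head, tail) type signature."""

    DIS_SYM = "DIS-SYM"
    DIS_OPE = "DIS-OPE"
    DIS_XW = "DIS-XW"
    OPE_XW = "OPE-XW"
    OPE_FUN = "OPE-FUN"
    XW_FUN = "XW-FUN"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def head_type(self) -> EntityType:
        return _SIGNATURES[self][0]

    @property
    def tail_type(self) -> EntityType:
        return _SIGNATURES[self][1]


_SIGNATURES: dict[RelationType, tuple[EntityType, EntityType]] = {
    RelationType.DIS_SYM: (EntityType.DIS, EntityType.SYM),
    RelationType.DIS_OPE: (EntityType.DIS, EntityType.OPE),
    RelationType.DIS_XW: (EntityType.DIS, EntityType.XW),
    RelationType.OPE_XW: (EntityType.OPE, EntityType.XW),
    RelationType.OPE_FUN: (EntityType.OPE, EntityType.FUN),
    RelationType.XW_FUN: (EntityType.XW, EntityType.FUN),
}

#: Valid (head_type, tail_type) -> RelationType lookup.
RELATION_BY_SIGNATURE: dict[tuple[EntityType, EntityType], RelationType] = {
    sig: rel for rel, sig in _SIGNATURES.items()
}


def normalize_surface(surface: str) -> str:
    """NFC-normalize and trim an entity surface form."""
    return unicodedata.normalize("NFC", surface).strip()


@dataclass(frozen=True)
class Triple:
    """A typed relation instance ``head -[relation]-> tail`` with provenance.

    Provenance is a free-form tag such as ``"structured_kb"`` or a
    ``(doc_id, sentence_index, rule_name)`` string for rule-extracted triples.
    Construction validates the endpoint types against the relation signature.
    """

    head: str
    head_type: EntityType
    relation: RelationType
    tail: str
    tail_type: EntityType
    provenance: str = ""

    def __post_init__(self) -> None:
        if (self.head_type, self.tail_type) != (
            self.relation.head_type,
            self.relation.tail_type,
        ):
            raise ValueError(
                f"triple ({self.head_type}, {self.tail_type}) violates "
                f"{self.relation.value} signature "
                f"({self.relation.head_type}, {self.relation.tail_type})"
            )

    def key(self) -> tuple[str, str, str]:
        """Identity of the triple ignoring provenance."""
        return (self.head, self.relation.value, self.tail)


@dataclass
class DiseaseRecord:
    """A structured disease entry: name, hospital section(s), site(s), symptoms."""

    name: str
    section: list[str] = field(default_factory=list)
    site: list[str] = field(default_factory=list)
    symptoms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.name.strip():
            raise ValueError("disease record requires a non-empty name")
        # preserve first-seen order while deduplicating
        seen: dict[str, None] = {}
        for s in self.symptoms:
            s = normalize_surface(s)
            if s:
                seen.setdefault(s)
        self.symptoms = list(seen)


@dataclass
class AcupointRecord:
    """A structured acupoint entry: name, meridian, functions, operation method."""

    name: str
    meridian: str = ""
    functions: list[str] = field(default_factory=list)
    operation_method: str = ""

    def __post_init__(self) -> None:
        if not self.name.strip():
            raise ValueError("acupoint record requires a non-empty name")


@dataclass
class DiseaseScopeLexicon:
    """Term lists deciding the disease-vs-symptom scope question.

    Membership is exact string equality after whitespace normalization; the
    term lists are user-supplied (one term per line), typically derived from
    ICD-10 and GB/T 16751.1.
    """

    icd10_terms: set[str] = field(default_factory=set)
    gbt_terms: set[str] = field(default_factory=set)

    @staticmethod
    def _norm(term: str) -> str:
        return re.sub(r"\s+", "", unicodedata.normalize("NFC", term))

    @classmethod
    def from_files(
        cls, icd10_path: str | Path | None = None, gbt_path: str | Path | None = None
    ) -> "DiseaseScopeLexicon":
        def load(p: str | Path | None) -> set[str]:
            if p is None:
                return set()
            lines = Path(p).read_text(encoding="utf-8").splitlines()
            return {cls._norm(t) for t in lines if t.strip()}

        return cls(icd10_terms=load(icd10_path), gbt_terms=load(gbt_path))

    def __post_init__(self) -> None:
        self.icd10_terms = {self._norm(t) for t in self.icd10_terms}
        self.gbt_terms = {self._norm(t) for t in self.gbt_terms}

    def __contains__(self, surface: str) -> bool:
        return self._norm(surface) in self.icd10_terms or self._norm(surface) in self.gbt_terms


def classify_disease_or_symptom(surface: str, lexicon: DiseaseScopeLexicon) -> EntityType:
    """Apply the scope rule: in-lexicon surfaces are diseases, the rest symptoms."""
    if not surface or not surface.strip():
        raise ValueError("cannot classify an empty surface form")
    return EntityType.DIS if surface in lexicon else EntityType.SYM


def ingest_disease_record(rec: DiseaseRecord) -> list[Triple]:
    """Turn a disease record into DIS-SYM triples, one per listed symptom."""
    head = normalize_surface(rec.name)
    return [
        Triple(head, EntityType.DIS, RelationType.DIS_SYM, sym, EntityType.SYM, "structured_kb")
        for sym in rec.symptoms
    ]


_FUNCTION_SPLIT = re.compile(r"[;；]")
_INDICATION_SPLIT = re.compile(r"[:：]")


def split_function_phrases(functions: str | Sequence[str]) -> list[str]:
    """Split a raw functions field on (Chinese) semicolons into phrases.

    A colon inside a phrase introduces indications ("Invigorate the meridians:
    Migraine"); only the pre-colon function phrase is kept, because the schema
    has no acupoint-disease relation.
    """
    if isinstance(functions, str):
        parts = _FUNCTION_SPLIT.split(functions)
    else:
        parts = [p for f in functions for p in _FUNCTION_SPLIT.split(f)]
    out: dict[str, None] = {}
    for p in parts:
        p = normalize_surface(_INDICATION_SPLIT.split(p)[0])
        if p:
            out.setdefault(p)
    return list(out)


def ingest_acupoint_record(rec: AcupointRecord) -> tuple[dict, list[Triple]]:
    """Turn an acupoint record into a node-attribute dict and XW-FUN triples.

    The meridian and operation method become attributes of the acupoint node;
    each parsed function phrase yields one XW-FUN triple.
    """
    head = normalize_surface(rec.name)
    attrs = {
        "surface": head,
        "etype": EntityType.XW,
        "meridian": normalize_surface(rec.meridian),
        "operation_method": normalize_surface(rec.operation_method),
    }
    phrases = split_function_phrases(rec.functions)
    triples = [
        Triple(head, EntityType.XW, RelationType.XW_FUN, fun, EntityType.FUN, "structured_kb")
        for fun in phrases
    ]
    return attrs, triples


def read_disease_records(path: str | Path) -> list[DiseaseRecord]:
    """Read disease records from CSV with Disease/Section/Site of disease/Symptom columns."""
    recs = []
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            recs.append(
                DiseaseRecord(
                    name=row.get("Disease", "").strip(),
                    section=_split_list(row.get("Section", "")),
                    site=_split_list(row.get("Site of disease", "")),
                    symptoms=_split_list(row.get("Symptom", "")),
                )
            )
    return recs


def read_acupoint_records(path: str | Path) -> list[AcupointRecord]:
    """Read acupoint records from CSV with Acupoint/Attributed meridians/Functions/Method of operation columns."""
    recs = []
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            recs.append(
                AcupointRecord(
                    name=row.get("Acupoint", "").strip(),
                    meridian=row.get("Attributed meridians", "").strip(),
                    functions=_split_list(row.get("Functions", "")),
                    operation_method=row.get("Method of operation", "").strip(),
                )
            )
    return recs


def _split_list(cell: str) -> list[str]:
    return [p.strip() for p in re.split(r"[;；]", cell) if p.strip()]
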