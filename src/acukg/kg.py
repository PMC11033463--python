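"""Knowledge-graph assembly, querying, statistics and export.

The graph is a typed multigraph: nodes are entity surface forms (NFC-
normalized) carrying an entity type, attributes and a corpus occurrence
count; edges are relation triples with provenance.  Assembly applies the
isolated-node filter: an entity known only from the dictionary is admitted
only if it occurs in the corpus at least once, because a dictionary-only
entity has no chance of carrying a relation and would sit in the graph as a
degree-zero node.  Entities discovered by the model or ingested from the
structured knowledge base are always admitted.  Triples whose endpoints were
filtered out are dropped and counted, never resurrected.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx

from .schema import EntityType, RelationType, Triple, normalize_surface
from .trie import DomainDictionary


@dataclass
class KnowledgeGraph:
    """Typed multigraph of entities and relation triples."""

    graph: nx.MultiDiGraph = field(default_factory=nx.MultiDiGraph)
    dropped_triples: int = 0
    excluded_dictionary_entries: int = 0

    # -- construction ------------------------------------------------------

    def add_entity(
        self,
        surface: str,
        etype: EntityType,
        attributes: Mapping[str, str] | None = None,
        occurrences: int = 0,
    ) -> str:
        surface = normalize_surface(surface)
        if surface in self.graph:
            prev = self.graph.nodes[surface]["etype"]
            if prev != etype:
                raise ValueError(
                    f"node {surface!r} already typed {prev.value}, cannot retype {etype.value}"
                )
            self.graph.nodes[surface]["occurrences"] += occurrences
            if attributes:
                self.graph.nodes[surface]["attributes"].update(attributes)
        else:
            self.graph.add_node(
                surface,
                etype=etype,
                attributes=dict(attributes or {}),
                occurrences=occurrences,
            )
        return surface

    def add_triple(self, triple: Triple) -> bool:
        """Add an edge if both endpoints exist; returns False (and counts) otherwise."""
        head = normalize_surface(triple.head)
        tail = normalize_surface(triple.tail)
        if head == tail:
            self.dropped_triples += 1
            return False
        if head not in self.graph or tail not in self.graph:
            self.dropped_triples += 1
            return False
        # skip exact duplicates (same head, tail, relation)
        for key, data in (self.graph.get_edge_data(head, tail) or {}).items():
            if data["relation"] == triple.relation:
                return True
        self.graph.add_edge(head, tail, relation=triple.relation, provenance=triple.provenance)
        return True

    # -- queries -----------------------------------------------------------

    @property
    def nodes(self) -> dict[str, dict]:
        return dict(self.graph.nodes(data=True))

    def triples(self) -> list[Triple]:
        out = []
        for head, tail, data in self.graph.edges(data=True):
            out.append(
                Triple(
                    head,
                    self.graph.nodes[head]["etype"],
                    data["relation"],
                    tail,
                    self.graph.nodes[tail]["etype"],
                    data.get("provenance", ""),
                )
            )
        return out

    def one_hop(self, surface: str) -> dict:
        """All neighbors of a node at distance one, grouped by relation type.

        Returns ``{"found": bool, "entity": ..., "etype": ..., "relations":
        {relation: sorted neighbor surfaces}}``; outgoing and incoming edges
        both count as neighbors.
        """
        surface = normalize_surface(surface)
        if surface not in self.graph:
            return {"found": False, "entity": surface, "etype": None, "relations": {}}
        grouped: dict[str, set[str]] = {}
        for _, tail, data in self.graph.out_edges(surface, data=True):
            grouped.setdefault(data["relation"].value, set()).add(tail)
        for head, _, data in self.graph.in_edges(surface, data=True):
            grouped.setdefault(data["relation"].value, set()).add(head)
        return {
            "found": True,
            "entity": surface,
            "etype": self.graph.nodes[surface]["etype"].value,
            "relations": {rel: sorted(nbrs) for rel, nbrs in sorted(grouped.items())},
        }

    def stats(self) -> dict:
        """Per-type entity and relation counts plus (asserted-consistent) totals."""
        entity_counts = {t.value: 0 for t in EntityType}
        for _, data in self.graph.nodes(data=True):
            entity_counts[data["etype"].value] += 1
        relation_counts = {r.value: 0 for r in RelationType}
        for _, _, data in self.graph.edges(data=True):
            relation_counts[data["relation"].value] += 1
        total_e = sum(entity_counts.values())
        total_r = sum(relation_counts.values())
        assert total_e == self.graph.number_of_nodes()
        assert total_r == self.graph.number_of_edges()
        return {
            "entity_counts": entity_counts,
            "entity_total": total_e,
            "relation_counts": relation_counts,
            "relation_total": total_r,
            "dropped_triples": self.dropped_triples,
        }

    # -- export ------------------------------------------------------------

    def export(self, path: str | Path, fmt: str) -> None:
        if fmt == "cypher":
            self._export_cypher(Path(path))
        elif fmt == "graphml":
            self._export_graphml(Path(path))
        elif fmt == "csv":
            self._export_csv(Path(path))
        else:
            raise ValueError(f"unknown export format {fmt!r}; use cypher, graphml or csv")

    def _export_cypher(self, path: Path) -> None:
        """MERGE statements loadable into a property-graph database."""
        lines = []
        for surface, data in sorted(self.graph.nodes(data=True)):
            props = {"name": surface, **data["attributes"]}
            prop_s = ", ".join(f"{k}: {json.dumps(str(v), ensure_ascii=False)}" for k, v in props.items())
            lines.append(f"MERGE (:{data['etype'].value} {{{prop_s}}});")
        for head, tail, data in sorted(self.graph.edges(data=True), key=lambda e: (e[0], e[1], e[2]["relation"].value)):
            rel = data["relation"].value.replace("-", "_")
            lines.append(
                "MATCH (h {name: %s}), (t {name: %s}) MERGE (h)-[:%s]->(t);"
                % (json.dumps(head, ensure_ascii=False), json.dumps(tail, ensure_ascii=False), rel)
            )
        path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")

    def _export_graphml(self, path: Path) -> None:
        g = nx.MultiDiGraph()
        for surface, data in self.graph.nodes(data=True):
            g.add_node(
                surface,
                etype=data["etype"].value,
                occurrences=data["occurrences"],
                attributes=json.dumps(data["attributes"], ensure_ascii=False),
            )
        for head, tail, data in self.graph.edges(data=True):
            g.add_edge(head, tail, relation=data["relation"].value, provenance=data.get("provenance", ""))
        nx.write_graphml(g, path)

    def _export_csv(self, path: Path) -> None:
        """nodes.csv + edges.csv under ``path`` (a directory)."""
        path.mkdir(parents=True, exist_ok=True)
        with open(path / "nodes.csv", "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["surface", "etype", "occurrences", "attributes"])
            for surface, data in sorted(self.graph.nodes(data=True)):
                w.writerow(
                    [surface, data["etype"].value, data["occurrences"],
                     json.dumps(data["attributes"], ensure_ascii=False)]
                )
        with open(path / "edges.csv", "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["head", "relation", "tail", "provenance"])
            for head, tail, data in sorted(
                self.graph.edges(data=True), key=lambda e: (e[0], e[1], e[2]["relation"].value)
            ):
                w.writerow([head, data["relation"].value, tail, data.get("provenance", "")])

    @classmethod
    def from_csv(cls, path: str | Path) -> "KnowledgeGraph":
        path = Path(path)
        kg = cls()
        with open(path / "nodes.csv", encoding="utf-8", newline="") as fh:
            for row in csv.DictReader(fh):
                kg.add_entity(
                    row["surface"],
                    EntityType(row["etype"]),
                    json.loads(row["attributes"]),
                    int(row["occurrences"]),
                )
        with open(path / "edges.csv", encoding="utf-8", newline="") as fh:
            for row in csv.DictReader(fh):
                kg.add_triple(
                    Triple(
                        row["head"],
                        kg.graph.nodes[normalize_surface(row["head"])]["etype"],
                        RelationType(row["relation"]),
                        row["tail"],
                        kg.graph.nodes[normalize_surface(row["tail"])]["etype"],
                        row.get("provenance", ""),
                    )
                )
        return kg


def build_graph(
    dictionary: DomainDictionary | None,
    corpus_entities: Sequence[tuple[str, EntityType, str]],
    kb_entities: Sequence[tuple[str, EntityType, Mapping[str, str]]] = (),
    kb_triples: Sequence[Triple] = (),
    rule_triples: Sequence[Triple] = (),
) -> KnowledgeGraph:
    """Assemble the graph with the isolated-node filter.

    ``corpus_entities`` are (surface, type, source) occurrences found in text
    (source "trie"/"model"/"fused"); each occurrence increments the node's
    count.  Dictionary entries never seen in the corpus are excluded; model-
    found and KB entities are always included.
    """
    kg = KnowledgeGraph()
    for surface, etype, source in corpus_entities:
        kg.add_entity(surface, etype, occurrences=1)
    if dictionary is not None:
        kg.excluded_dictionary_entries = sum(
            1 for s in dictionary.entries if normalize_surface(s) not in kg.graph
        )
    for surface, etype, attrs in kb_entities:
        kg.add_entity(surface, etype, attributes=attrs)
    for tri in kb_triples:
        # KB triples vouch for both endpoints (direct population of the graph)
        kg.add_entity(tri.head, tri.head_type)
        kg.add_entity(tri.tail, tri.tail_type)
        kg.add_triple(tri)
    for tri in rule_triples:
        kg.add_triple(tri)
    return kg


def one_hop_query(kg: KnowledgeGraph, surface: str) -> dict:
    """Functional wrapper over :meth:`KnowledgeGraph.one_hop`."""
    return kg.one_hop(surface)


def kg_stats(kg: KnowledgeGraph) -> dict:
    """Functional wrapper over :meth:`KnowledgeGraph.stats`."""
    return kg.stats()
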