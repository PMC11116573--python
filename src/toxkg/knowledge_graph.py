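"""Provenance-tracked compound/phenotype knowledge graph.

Relations extracted from the literature are merged into a directed graph:
one node per normalized entity key, one edge per ordered (cause, effect)
pair with the set of causal verbs observed and an evidence record per
(article, sentence, verb) so every edge is retraceable to the exact
sentence it came from.  First-level-neighbor queries answer the screening
question "which compounds are linked to this adverse outcome?".

Exports target a bulk-loaded graph database (Neo4j ``neo4j-admin import``
CSV dialect), generic tooling (GraphML via networkx) and live sessions
(Cypher MERGE script).  All exports are byte-deterministic functions of
the graph.
"""

from __future__ import annotations

import csv
import io
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

from .causal_relex import CausalRelation

__all__ = [
    "Evidence",
    "KGNode",
    "KGEdge",
    "KnowledgeGraph",
    "build_graph",
    "neighbors",
    "export_neo4j_csv",
    "export_graphml",
    "export_cypher",
]


@dataclass(frozen=True)
class Evidence:
    """One supporting sentence for an edge."""

    doc_id: str
    sent_id: str
    verb_lemma: str
    sentence_text: str


@dataclass
class KGNode:
    key: str
    label_counts: Counter = field(default_factory=Counter)
    surfaces: set[str] = field(default_factory=set)
    mention_count: int = 0

    @property
    def label(self) -> str:
        """Majority label; a tie between COMPOUND and PHENOTYPE resolves to
        COMPOUND (both counts stay available in ``label_counts``)."""
        if not self.label_counts:
            return "COMPOUND"
        best = max(self.label_counts.values())
        winners = sorted(k for k, v in self.label_counts.items() if v == best)
        return "COMPOUND" if "COMPOUND" in winners else winners[0]

    @property
    def name(self) -> str:
        """Display name: the most frequently observed surface form would
        need per-surface counts; we use the lexicographically smallest
        surface for determinism."""
        return min(self.surfaces) if self.surfaces else self.key


@dataclass
class KGEdge:
    source_key: str
    target_key: str
    verb_lemmas: set[str] = field(default_factory=set)
    evidence: list[Evidence] = field(default_factory=list)

    @property
    def evidence_count(self) -> int:
        return len(self.evidence)


@dataclass
class KnowledgeGraph:
    nodes: dict[str, KGNode] = field(default_factory=dict)
    edges: dict[tuple[str, str], KGEdge] = field(default_factory=dict)

    @property
    def total_evidence(self) -> int:
        return sum(e.evidence_count for e in self.edges.values())


def build_graph(relations: Iterable[CausalRelation]) -> KnowledgeGraph:
    """Merge relations into a graph.

    Nodes are upserted from mention keys and labels; one directed edge is
    kept per (cause key, effect key) with merged verb sets and evidence
    deduplicated by (doc_id, sent_id, verb, source, target).  The total
    evidence count therefore equals the number of unique input relations.
    Output collections are key-sorted, so the result does not depend on
    input order beyond first-seen surface sets (which are sets anyway).
    """
    graph = KnowledgeGraph()
    seen_evidence: set[tuple[str, str, str, str, str]] = set()
    for rel in relations:
        sig = (rel.doc_id, rel.sent_id, rel.verb_lemma, rel.cause.key, rel.effect.key)
        if sig in seen_evidence:
            continue
        seen_evidence.add(sig)
        for mention in (rel.cause, rel.effect):
            node = graph.nodes.setdefault(mention.key, KGNode(key=mention.key))
            node.label_counts[mention.label] += 1
            node.surfaces.add(mention.surface)
            node.mention_count += 1
        edge = graph.edges.setdefault(
            (rel.cause.key, rel.effect.key),
            KGEdge(source_key=rel.cause.key, target_key=rel.effect.key),
        )
        edge.verb_lemmas.add(rel.verb_lemma)
        edge.evidence.append(Evidence(
            doc_id=rel.doc_id, sent_id=rel.sent_id,
            verb_lemma=rel.verb_lemma, sentence_text=rel.sentence_text,
        ))
    graph.nodes = dict(sorted(graph.nodes.items()))
    graph.edges = dict(sorted(graph.edges.items()))
    return graph


def neighbors(graph: KnowledgeGraph, key: str,
              label_filter: str | None = None,
              direction: str = "ANY") -> list[KGNode]:
    """First-level neighbors of a node, key-sorted.

    ``direction`` is ``OUT`` (successors), ``IN`` (predecessors) or ``ANY``;
    an unknown key yields an empty list.  This is the query used for the
    adverse-outcome compound screen (e.g. all COMPOUND neighbors of
    "cholestasis").
    """
    if direction not in {"IN", "OUT", "ANY"}:
        raise ValueError(f"direction must be IN, OUT or ANY, got {direction!r}")
    found: set[str] = set()
    for src, dst in graph.edges:
        if src == key and direction in {"OUT", "ANY"}:
            found.add(dst)
        if dst == key and direction in {"IN", "ANY"}:
            found.add(src)
    found.discard(key)
    out = [graph.nodes[k] for k in sorted(found)]
    if label_filter is not None:
        out = [n for n in out if n.label == label_filter]
    return out


def export_neo4j_csv(graph: KnowledgeGraph, out_dir: str | Path) -> tuple[Path, Path]:
    """Write ``nodes.csv`` and ``edges.csv`` in the bulk-import dialect.

    Headers: ``key:ID,label,name,mention_count:int`` and
    ``:START_ID,:END_ID,:TYPE,verbs,evidence_count:int,doc_ids``.  Rows are
    lexicographically sorted, RFC-4180 quoted, byte-deterministic.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nodes_path = out_dir / "nodes.csv"
    edges_path = out_dir / "edges.csv"

    with nodes_path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\r\n")
        writer.writerow(["key:ID", "label", "name", "mention_count:int"])
        for key in sorted(graph.nodes):
            node = graph.nodes[key]
            writer.writerow([key, node.label, node.name, node.mention_count])

    with edges_path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\r\n")
        writer.writerow([":START_ID", ":END_ID", ":TYPE", "verbs",
                         "evidence_count:int", "doc_ids"])
        for (src, dst) in sorted(graph.edges):
            edge = graph.edges[(src, dst)]
            verbs = ";".join(sorted(edge.verb_lemmas))
            doc_ids = ";".join(sorted({e.doc_id for e in edge.evidence}))
            writer.writerow([src, dst, "CAUSES", verbs, edge.evidence_count, doc_ids])
    return nodes_path, edges_path


def to_networkx(graph: KnowledgeGraph) -> nx.DiGraph:
    """View of the graph as a networkx DiGraph with export-ready attributes."""
    g = nx.DiGraph()
    for key in sorted(graph.nodes):
        node = graph.nodes[key]
        g.add_node(key, label=node.label, name=node.name,
                   mention_count=node.mention_count)
    for (src, dst) in sorted(graph.edges):
        edge = graph.edges[(src, dst)]
        g.add_edge(src, dst,
                   verbs=";".join(sorted(edge.verb_lemmas)),
                   evidence_count=edge.evidence_count,
                   doc_ids=";".join(sorted({e.doc_id for e in edge.evidence})))
    return g


def export_graphml(graph: KnowledgeGraph) -> str:
    """GraphML serialization with declared node/edge attribute keys."""
    buf = io.BytesIO()
    nx.write_graphml(to_networkx(graph), buf, named_key_ids=True)
    return buf.getvalue().decode("utf-8")


def _cypher_quote(value: str) -> str:
    return "'" + value.replace("\\", "\\\\").replace("'", "\\'") + "'"


def export_cypher(graph: KnowledgeGraph) -> str:
    """Cypher MERGE script loadable against a live database: one MERGE per
    node, one per relationship, key-sorted."""
    lines = []
    for key in sorted(graph.nodes):
        node = graph.nodes[key]
        lines.append(
            f"MERGE (n:{node.label} {{key: {_cypher_quote(key)}}}) "
            f"SET n.name = {_cypher_quote(node.name)}, n.mention_count = {node.mention_count};"
        )
    for (src, dst) in sorted(graph.edges):
        edge = graph.edges[(src, dst)]
        verbs = ", ".join(_cypher_quote(v) for v in sorted(edge.verb_lemmas))
        lines.append(
            f"MATCH (a {{key: {_cypher_quote(src)}}}), (b {{key: {_cypher_quote(dst)}}}) "
            f"MERGE (a)-[r:CAUSES]->(b) "
            f"SET r.verbs = [{verbs}], r.evidence_count = {edge.evidence_count};"
        )
    return "\n".join(lines) + ("\n" if lines else "")
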