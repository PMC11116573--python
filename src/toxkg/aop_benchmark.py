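"""Recovery of adverse outcome pathways from an extracted graph.

An AOP reference is a small directed graph of events — a molecular
initiating event (MIE), intermediate key events (KE) and an adverse
outcome (AO) — connected by key event relationships (KERs).  References
are hand-transcribed from AOPWiki into a simple JSON schema (no live
access needed):

.. code-block:: json

    {
      "aop_id": "36",
      "title": "...",
      "events": [{"event_id": "459", "title": "Increased, Liver Steatosis",
                  "type": "AO"}, ...],
      "kers": [{"upstream": "459", "downstream": "..."}, ...]
    }

The benchmark matches each event title to a graph node by token-set
similarity (after stripping directionality qualifiers such as
"Increased,"), then checks which KERs have a supporting edge between the
matched nodes, and flags *shortcut* edges: extracted links between events
that are non-adjacent in the reference, e.g. an MIE connected directly to
the AO.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import IO

from .knowledge_graph import KnowledgeGraph

__all__ = [
    "AOPEvent",
    "AOPReference",
    "ComparisonReport",
    "load_aop_reference",
    "normalize_event_title",
    "match_events",
    "ker_recovery",
    "compare",
]

EVENT_TYPES = ("MIE", "KE", "AO")


@dataclass(frozen=True)
class AOPEvent:
    event_id: str
    title: str
    type: str


@dataclass
class AOPReference:
    """Events and KERs of one reference pathway.

    References with fewer than two events load but carry
    ``excluded_single_event=True``: a one-event pathway has no KERs to
    recover and is left out of fraction aggregation.
    """

    aop_id: str
    title: str
    events: list[AOPEvent]
    kers: list[tuple[str, str]]
    excluded_single_event: bool = False


@dataclass
class ComparisonReport:
    aop_id: str
    matched_events: dict[str, str] = field(default_factory=dict)
    event_fraction: float = 0.0
    matched_kers: list[tuple[str, str]] = field(default_factory=list)
    ker_fraction: float = 0.0
    shortcuts: list[tuple[tuple[str, str], int]] = field(default_factory=list)
    excluded_single_event: bool = False

    def to_dict(self) -> dict:
        return {
            "aop_id": self.aop_id,
            "matched_events": dict(sorted(self.matched_events.items())),
            "event_fraction": self.event_fraction,
            "matched_kers": [list(k) for k in self.matched_kers],
            "ker_fraction": self.ker_fraction,
            "shortcuts": [{"nodes": list(pair), "path_length": ln}
                          for pair, ln in self.shortcuts],
            "excluded_single_event": self.excluded_single_event,
        }


def load_aop_reference(stream: str | bytes | IO) -> AOPReference:
    """Load and validate an AOP reference from JSON.

    Schema violations raise ``ValueError`` naming the offending field;
    KERs must reference declared event ids; event ids must be unique.
    """
    if hasattr(stream, "read"):
        stream = stream.read()
    try:
        obj = json.loads(stream)
    except json.JSONDecodeError as exc:
        raise ValueError(f"AOP reference: invalid JSON: {exc}") from exc

    for fld in ("aop_id", "title", "events", "kers"):
        if fld not in obj:
            raise ValueError(f"AOP reference: missing field {fld!r}")
    events = []
    seen_ids = set()
    if not obj["events"]:
        raise ValueError("AOP reference: field 'events' must contain at least one event")
    for i, ev in enumerate(obj["events"]):
        for fld in ("event_id", "title", "type"):
            if fld not in ev:
                raise ValueError(f"AOP reference: events[{i}] missing field {fld!r}")
        if ev["type"] not in EVENT_TYPES:
            raise ValueError(
                f"AOP reference: events[{i}].type {ev['type']!r} not in {EVENT_TYPES}")
        eid = str(ev["event_id"])
        if eid in seen_ids:
            raise ValueError(f"AOP reference: duplicate event_id {eid!r}")
        seen_ids.add(eid)
        events.append(AOPEvent(event_id=eid, title=str(ev["title"]), type=ev["type"]))
    kers = []
    for i, ker in enumerate(obj["kers"]):
        up, down = str(ker.get("upstream", "")), str(ker.get("downstream", ""))
        for name, val in (("upstream", up), ("downstream", down)):
            if val not in seen_ids:
                raise ValueError(
                    f"AOP reference: kers[{i}].{name} {val!r} is not a declared event_id")
        kers.append((up, down))
    return AOPReference(
        aop_id=str(obj["aop_id"]), title=str(obj["title"]),
        events=events, kers=kers,
        excluded_single_event=len(events) < 2,
    )


_QUALIFIER_RE = re.compile(r"^\s*\w+\s*,\s*")


def normalize_event_title(title: str) -> str:
    """Match-key of an AOPWiki event title.

    AOPWiki titles prefix a directionality qualifier before a comma
    ("Increased, Liver Steatosis", "Decreased, ..."); the leading
    single-word qualifier is stripped, then the remainder is lowercased,
    punctuation-stripped and whitespace-collapsed.
    """
    stripped = _QUALIFIER_RE.sub("", title, count=1)
    stripped = re.sub(r"[^\w\s-]", " ", stripped.lower())
    stripped = stripped.replace("-", " ")
    return re.sub(r"\s+", " ", stripped).strip()


def _token_set(text: str) -> frozenset[str]:
    return frozenset(text.split())


def _iou(a: frozenset[str], b: frozenset[str]) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def match_events(reference: AOPReference, graph: KnowledgeGraph,
                 threshold: float = 0.8) -> dict[str, str]:
    """Match each reference event to its most similar graph node.

    Similarity is intersection-over-union of normalized token sets between
    the event's match-key and the node key; an event matches only at
    similarity >= ``threshold``, ties go to the lexicographically smallest
    node key.  One node may legitimately match several events (AOPWiki
    carries near-duplicate events like "Increased, Liver Steatosis" vs
    "Increased, steatosis").
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    node_tokens = {key: _token_set(normalize_event_title(key)) for key in graph.nodes}
    matches: dict[str, str] = {}
    for event in reference.events:
        ev_tokens = _token_set(normalize_event_title(event.title))
        best_key, best_sim = None, 0.0
        for key in sorted(node_tokens):
            sim = _iou(ev_tokens, node_tokens[key])
            if sim > best_sim:
                best_key, best_sim = key, sim
        if best_key is not None and best_sim >= threshold:
            matches[event.event_id] = best_key
    return matches


def _has_edge(graph: KnowledgeGraph, a: str, b: str, strict: bool) -> bool:
    if (a, b) in graph.edges:
        return True
    return not strict and (b, a) in graph.edges


def _path_lengths(reference: AOPReference) -> dict[tuple[str, str], int]:
    """Shortest directed path length between every ordered event pair
    (breadth-first over the KER graph)."""
    adj: dict[str, list[str]] = {}
    for up, down in reference.kers:
        adj.setdefault(up, []).append(down)
    lengths: dict[tuple[str, str], int] = {}
    for start in (e.event_id for e in reference.events):
        frontier, dist = [start], 0
        seen = {start}
        while frontier:
            dist += 1
            nxt = []
            for node in frontier:
                for succ in adj.get(node, []):
                    if succ not in seen:
                        seen.add(succ)
                        lengths[(start, succ)] = dist
                        nxt.append(succ)
            frontier = nxt
    return lengths


def ker_recovery(reference: AOPReference, graph: KnowledgeGraph,
                 matches: dict[str, str], strict_direction: bool = False,
                 ) -> tuple[list[tuple[str, str]], list[tuple[tuple[str, str], int]]]:
    """Recovered KERs and shortcut links.

    A KER is recovered when both endpoint events matched graph nodes and an
    edge exists between them (direction-agnostic unless
    ``strict_direction``, since the extractor's orientation is heuristic).
    A shortcut is an extracted edge between matched events that the
    reference connects only through a directed path of length >= 2 (e.g.
    bile accumulation linked straight to cholestasis across intermediate
    key events).
    """
    matched_kers = [
        (up, down) for up, down in reference.kers
        if up in matches and down in matches
        and matches[up] != matches[down]
        and _has_edge(graph, matches[up], matches[down], strict_direction)
    ]
    shortcuts: list[tuple[tuple[str, str], int]] = []
    seen_pairs: set[tuple[str, str]] = set()
    lengths = _path_lengths(reference)
    for (up, down), dist in sorted(lengths.items()):
        if dist < 2 or up not in matches or down not in matches:
            continue
        a, b = matches[up], matches[down]
        if a == b or (a, b) in seen_pairs:
            continue
        if _has_edge(graph, a, b, strict_direction):
            seen_pairs.add((a, b))
            shortcuts.append(((a, b), dist))
    return matched_kers, shortcuts


def compare(reference: AOPReference, graph: KnowledgeGraph,
            threshold: float = 0.8, strict_direction: bool = False,
            ) -> ComparisonReport:
    """Full event- and KER-recovery report of a graph against a reference."""
    matches = match_events(reference, graph, threshold=threshold)
    matched_kers, shortcuts = ker_recovery(reference, graph, matches,
                                           strict_direction=strict_direction)
    n_events = len(reference.events)
    n_kers = len(reference.kers)
    return ComparisonReport(
        aop_id=reference.aop_id,
        matched_events=matches,
        event_fraction=len(matches) / n_events if n_events else 0.0,
        matched_kers=matched_kers,
        ker_fraction=len(matched_kers) / n_kers if n_kers else 0.0,
        shortcuts=shortcuts,
        excluded_single_event=reference.excluded_single_event,
    )
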