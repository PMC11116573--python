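"""AOP reference loading, event-title normalization, recovery scoring."""

import json
import random
from importlib import resources

import pytest

from toxkg.aop_benchmark import (AOPEvent, AOPReference, compare,
                                 ker_recovery, load_aop_reference,
                                 match_events, normalize_event_title)
from toxkg.causal_relex import extract_relations, load_causal_verbs
from toxkg.knowledge_graph import KGEdge, KGNode, KnowledgeGraph, build_graph

from conftest import random_mentions, random_sentence


def _graph_of(edges: list[tuple[str, str]]) -> KnowledgeGraph:
    graph = KnowledgeGraph()
    for src, dst in edges:
        for key in (src, dst):
            if key not in graph.nodes:
                node = KGNode(key=key)
                node.label_counts["PHENOTYPE"] += 1
                node.mention_count += 1
                graph.nodes[key] = node
        graph.edges[(src, dst)] = KGEdge(source_key=src, target_key=dst)
    return graph


def _reference(event_titles: list[str], kers: list[tuple[int, int]],
               aop_id: str = "test") -> AOPReference:
    events = [AOPEvent(event_id=f"E{i+1}", title=t, type="KE")
              for i, t in enumerate(event_titles)]
    return AOPReference(aop_id=aop_id, title="test", events=events,
                        kers=[(f"E{a}", f"E{b}") for a, b in kers])


class TestLoadReference:
    def test_shipped_synthetic_fixture_loads(self):
        text = resources.files("toxkg.data").joinpath("aop36_synthetic.json").read_text()
        ref = load_aop_reference(text)
        assert len(ref.events) == 4
        assert len(ref.kers) == 3
        assert not ref.excluded_single_event
        assert ref.events[0].type == "MIE"

    def test_single_event_reference_loadable_but_flagged(self):
        ref = load_aop_reference(json.dumps({
            "aop_id": "59", "title": "one-event", "kers": [],
            "events": [{"event_id": "1", "title": "x", "type": "MIE"}]}))
        assert ref.excluded_single_event

    def test_ker_naming_unknown_event_rejected(self):
        with pytest.raises(ValueError, match="upstream"):
            load_aop_reference(json.dumps({
                "aop_id": "1", "title": "t",
                "events": [{"event_id": "1", "title": "x", "type": "KE"}],
                "kers": [{"upstream": "99", "downstream": "1"}]}))

    def test_missing_field_named(self):
        with pytest.raises(ValueError, match="'events'"):
            load_aop_reference(json.dumps({"aop_id": "1", "title": "t", "kers": []}))

    def test_bad_event_type_rejected(self):
        with pytest.raises(ValueError, match="type"):
            load_aop_reference(json.dumps({
                "aop_id": "1", "title": "t", "kers": [],
                "events": [{"event_id": "1", "title": "x", "type": "EVENT"}]}))


class TestNormalizeEventTitle:
    @pytest.mark.parametrize("title, expected", [
        ("Increased, Liver Steatosis", "liver steatosis"),
        ("Increased, steatosis", "steatosis"),
        ("Decreased, fatty acid beta-oxidation", "fatty acid beta oxidation"),
        ("steatosis", "steatosis"),
        ("Occurrence,   cholestasis", "cholestasis"),
    ])
    def test_qualifier_stripping_and_lowercasing(self, title, expected):
        assert normalize_event_title(title) == expected


class TestMatchEvents:
    def test_exact_match_after_normalization(self):
        graph = _graph_of([("steatosis", "cholestasis")])
        ref = _reference(["Increased, steatosis"], [])
        assert match_events(ref, graph) == {"E1": "steatosis"}

    def test_partial_overlap_below_threshold_unmatched(self):
        graph = _graph_of([("steatosis", "cholestasis")])
        ref = _reference(["liver steatosis"], [])
        assert match_events(ref, graph) == {}  # IoU 1/2 < 0.8

    def test_threshold_monotonicity(self):
        graph = _graph_of([("steatosis", "cholestasis")])
        ref = _reference(["liver steatosis", "Increased, cholestasis"], [])
        strict = match_events(ref, graph, threshold=0.8)
        loose = match_events(ref, graph, threshold=0.5)
        assert set(strict) <= set(loose)
        assert loose["E1"] == "steatosis"

    def test_one_node_may_match_multiple_events(self):
        graph = _graph_of([("steatosis", "cholestasis")])
        ref = _reference(["Increased, steatosis", "Increased, Steatosis"], [])
        matches = match_events(ref, graph)
        assert matches == {"E1": "steatosis", "E2": "steatosis"}

    def test_empty_graph_no_matches(self):
        ref = _reference(["steatosis"], [])
        report = compare(ref, build_graph([]))
        assert report.matched_events == {}
        assert report.event_fraction == 0.0


class TestKerRecovery:
    def test_chain_with_direct_and_shortcut_edge(self):
        # reference A -> B -> C; extracted edges (A,B) and (A,C)
        ref = _reference(["aaa", "bbb", "ccc"], [(1, 2), (2, 3)])
        graph = _graph_of([("aaa", "bbb"), ("aaa", "ccc")])
        matches = match_events(ref, graph)
        matched, shortcuts = ker_recovery(ref, graph, matches)
        assert matched == [("E1", "E2")]
        assert shortcuts == [(("aaa", "ccc"), 2)]

    def test_direction_agnostic_by_default(self):
        ref = _reference(["aaa", "bbb"], [(1, 2)])
        graph = _graph_of([("bbb", "aaa")])  # reversed edge
        matches = match_events(ref, graph)
        assert ker_recovery(ref, graph, matches)[0] == [("E1", "E2")]
        assert ker_recovery(ref, graph, matches, strict_direction=True)[0] == []

    def test_no_matches_no_recovery(self):
        ref = _reference(["aaa", "bbb"], [(1, 2)])
        graph = _graph_of([("xxx", "yyy")])
        matched, shortcuts = ker_recovery(ref, graph, {})
        assert matched == [] and shortcuts == []

    def test_event_fraction_arithmetic(self):
        titles = [f"ev{i}" for i in range(10)]
        ref = _reference(titles, [(i, i + 1) for i in range(1, 10)])
        graph = _graph_of([(f"ev{i}", f"ev{i+1}") for i in range(6)])  # ev0..ev6 present
        report = compare(ref, graph)
        assert report.event_fraction == 0.7

    def test_shortcuts_agree_with_all_pairs_path_search(self):
        rng = random.Random(246)
        for _ in range(50):
            n = rng.randint(3, 12)
            titles = [f"node{i}" for i in range(n)]
            kers = sorted({(a, b) for _ in range(rng.randint(1, 2 * n))
                           for a in [rng.randint(1, n - 1)]
                           for b in [rng.randint(a + 1, n)]})
            ref = _reference(titles, kers)
            edges = sorted({(f"node{rng.randint(0, n-1)}", f"node{rng.randint(0, n-1)}")
                            for _ in range(rng.randint(1, n))})
            edges = [(a, b) for a, b in edges if a != b]
            graph = _graph_of(edges)
            matches = match_events(ref, graph)
            _, shortcuts = ker_recovery(ref, graph, matches)
            # oracle: brute-force path enumeration over all ordered pairs
            def paths_len(src, dst):
                best = [None]
                def walk(cur, dist, seen):
                    if cur == dst and dist > 0:
                        if best[0] is None or dist < best[0]:
                            best[0] = dist
                        return
                    for a, b in kers:
                        nxt = (f"E{a}", f"E{b}")
                        if nxt[0] == cur and nxt[1] not in seen:
                            walk(nxt[1], dist + 1, seen | {nxt[1]})
                walk(src, 0, {src})
                return best[0]
            expected = set()
            for e1 in matches:
                for e2 in matches:
                    d = paths_len(e1, e2)
                    if d is not None and d >= 2 and matches[e1] != matches[e2]:
                        pair = (matches[e1], matches[e2])
                        if (pair in graph.edges) or ((pair[1], pair[0]) in graph.edges):
                            expected.add((pair, d))
            assert set(shortcuts) == expected


class TestMonotonicity:
    def test_fractions_monotone_in_graph_growth(self):
        ref = _reference(["aaa", "bbb", "ccc", "ddd"], [(1, 2), (2, 3), (3, 4)])
        edges = [("aaa", "bbb"), ("bbb", "ccc"), ("ccc", "ddd")]
        prev_event, prev_ker = 0.0, 0.0
        for k in range(len(edges) + 1):
            report = compare(ref, _graph_of(edges[:k]))
            assert report.event_fraction >= prev_event
            assert report.ker_fraction >= prev_ker
            assert 0.0 <= report.event_fraction <= 1.0
            assert 0.0 <= report.ker_fraction <= 1.0
            prev_event, prev_ker = report.event_fraction, report.ker_fraction

    def test_extracted_graph_feeds_comparison(self, sent_active):
        from conftest import mention
        rels = extract_relations(sent_active, [
            mention(sent_active, 1, 1, "COMPOUND"),
            mention(sent_active, 3, 3, "PHENOTYPE")], load_causal_verbs())
        graph = build_graph(rels)
        ref = _reference(["Increased, steatosis"], [])
        assert compare(ref, graph).event_fraction == 1.0
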