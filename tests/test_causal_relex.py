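"""Causal relation extraction: verb config, ancestry, orientation, and
equivalence with a brute-force enumeration oracle."""

import random

import pytest

from toxkg.causal_relex import (DEFAULT_POLICY, CausalVerbSet,
                                common_causal_ancestors, entity_head,
                                extract_relations, load_causal_verbs, orient)
from toxkg.parse_layer import Sentence

from conftest import mention, random_mentions, random_sentence


class TestLoadCausalVerbs:
    def test_default_list_has_22_unique_lemmas(self):
        assert len(load_causal_verbs()) == 22

    @pytest.mark.parametrize("lemma, expected", [
        ("induce", True), ("cause", True), ("lead", True), ("diminish", True),
        ("study", False), ("measure", False),
    ])
    def test_membership(self, lemma, expected):
        assert (lemma in load_causal_verbs()) is expected

    def test_custom_list_lowercased_and_deduplicated(self):
        verbs = load_causal_verbs(["Induce", "induce", "CAUSE"])
        assert verbs.lemmas == frozenset({"induce", "cause"})

    def test_empty_config_rejected(self):
        with pytest.raises(ValueError):
            load_causal_verbs([])


class TestEntityHead:
    def test_multiword_agent_span(self, sent_passive):
        m = mention(sent_passive, 5, 6, "COMPOUND")
        assert entity_head(sent_passive, m) == 6

    def test_single_token_span(self, sent_active):
        assert entity_head(sent_active, mention(sent_active, 1, 1, "COMPOUND")) == 1

    def test_conjunct_span_head_outside(self, sent_coordinated):
        m = mention(sent_coordinated, 3, 4, "COMPOUND")
        assert entity_head(sent_coordinated, m) == 4


class TestCommonCausalAncestors:
    def test_active_fixture(self, sent_active):
        verbs = load_causal_verbs()
        assert common_causal_ancestors(sent_active, 1, 3, verbs) == [2]

    def test_coordinated_conjunct(self, sent_coordinated):
        verbs = load_causal_verbs()
        assert common_causal_ancestors(sent_coordinated, 4, 6, verbs) == [5]

    def test_lemma_mismatch_is_empty(self, sent_active):
        verbs = CausalVerbSet(lemmas=frozenset({"cause"}))
        assert common_causal_ancestors(sent_active, 3, 5, verbs) == []

    def test_strict_ancestry_excludes_entity_heads(self, sent_active):
        # token 2 itself as one of the "heads": may not be its own ancestor
        verbs = load_causal_verbs()
        assert common_causal_ancestors(sent_active, 2, 3, verbs) == []


class TestOrient:
    def test_active_nsubj_vs_obj(self, sent_active):
        a = mention(sent_active, 1, 1, "COMPOUND")
        b = mention(sent_active, 3, 3, "PHENOTYPE")
        cause, effect, method = orient(sent_active, 2, a, b)
        assert (cause.key, effect.key, method) == ("paracetamol", "steatosis", "SYNTACTIC")

    def test_passive_obl_agent_vs_nsubj_pass(self, sent_passive):
        a = mention(sent_passive, 1, 1, "PHENOTYPE")
        b = mention(sent_passive, 5, 6, "COMPOUND")
        cause, effect, method = orient(sent_passive, 3, a, b)
        assert (cause.key, effect.key, method) == ("valproic acid", "steatosis", "SYNTACTIC")

    def test_symmetric_in_argument_order(self, sent_passive):
        a = mention(sent_passive, 1, 1, "PHENOTYPE")
        b = mention(sent_passive, 5, 6, "COMPOUND")
        assert orient(sent_passive, 3, a, b) == orient(sent_passive, 3, b, a)

    def test_two_obliques_fall_back_to_linear_order(self, sent_active):
        # steatosis (obj) vs rats (obl): both effect-roles -> linear fallback
        a = mention(sent_active, 3, 3, "PHENOTYPE")
        b = mention(sent_active, 5, 5, "PHENOTYPE")
        cause, effect, method = orient(sent_active, 2, a, b)
        assert method == "LINEAR_FALLBACK"
        assert cause.first_token < effect.first_token


class TestExtractRelations:
    def test_active_fixture_single_relation(self, sent_active):
        mentions = [mention(sent_active, 1, 1, "COMPOUND"),
                    mention(sent_active, 3, 3, "PHENOTYPE")]
        rels = extract_relations(sent_active, mentions, load_causal_verbs())
        assert [(r.cause.key, r.effect.key, r.verb_lemma, r.orientation_method)
                for r in rels] == [("paracetamol", "steatosis", "induce", "SYNTACTIC")]

    def test_coordinated_subject_yields_both_conjuncts(self, sent_coordinated):
        mentions = [mention(sent_coordinated, 1, 1, "COMPOUND"),
                    mention(sent_coordinated, 3, 4, "COMPOUND"),
                    mention(sent_coordinated, 6, 6, "PHENOTYPE")]
        rels = extract_relations(sent_coordinated, mentions, load_causal_verbs())
        assert {(r.cause.key, r.effect.key, r.verb_lemma) for r in rels} == {
            ("naringin", "cholestasis", "induce"),
            ("valproic acid", "cholestasis", "induce"),
        }

    def test_non_causal_verb_yields_nothing(self, sent_active):
        mentions = [mention(sent_active, 1, 1, "COMPOUND"),
                    mention(sent_active, 3, 3, "PHENOTYPE")]
        verbs = CausalVerbSet(lemmas=frozenset({"study"}))
        assert extract_relations(sent_active, mentions, verbs) == []

    def test_compound_compound_pairs_skipped_by_default(self, sent_coordinated):
        mentions = [mention(sent_coordinated, 1, 1, "COMPOUND"),
                    mention(sent_coordinated, 3, 4, "COMPOUND")]
        assert extract_relations(sent_coordinated, mentions, load_causal_verbs()) == []

    def test_provenance_fields(self, sent_active):
        mentions = [mention(sent_active, 1, 1, "COMPOUND"),
                    mention(sent_active, 3, 3, "PHENOTYPE")]
        (rel,) = extract_relations(sent_active, mentions, load_causal_verbs())
        assert rel.doc_id == "fixture"
        assert rel.sent_id == "f1"
        assert rel.sentence_text == "Paracetamol induces steatosis in rats ."
        assert rel.verb_index == 2


# ---------------------------------------------------------------------------
# brute-force oracle


def _reaches(heads: dict[int, int], start: int, target: int) -> bool:
    cur = heads[start]
    while cur != 0:
        if cur == target:
            return True
        cur = heads[cur]
    return False


def _oracle_extract(sent: Sentence, mentions, verbs: CausalVerbSet):
    """Enumerate all mention pairs x all tokens; ancestry by repeated head
    lookup; independent re-derivation of orientation and dedup."""
    heads = {t.index: t.head for t in sent.tokens}

    def span_head(m):
        for i in range(m.first_token, m.last_token + 1):
            h = heads[i]
            if h == 0 or not m.first_token <= h <= m.last_token:
                return i

    def verb_child_toward(verb_idx, node):
        cur = node
        while heads[cur] != verb_idx:
            cur = heads[cur]
        return cur

    def role(deprel):
        cause = {"nsubj", "csubj", "obl:agent"}
        effect = {"obj", "iobj", "nsubj:pass", "csubj:pass", "obl",
                  "ccomp", "xcomp", "advcl", "nmod"}
        for lab in (deprel, deprel.split(":")[0]):
            if lab in cause:
                return "cause"
            if lab in effect:
                return "effect"
        return None

    def steps_to(start: int, target: int) -> int | None:
        cur, k = heads[start], 1
        while cur != 0:
            if cur == target:
                return k
            cur, k = heads[cur], k + 1
        return None

    out = set()
    for i in range(len(mentions)):
        for j in range(i + 1, len(mentions)):
            ma, mb = mentions[i], mentions[j]
            if ma.key == mb.key:
                continue
            if frozenset({ma.label, mb.label}) == frozenset({"COMPOUND"}):
                continue
            ha, hb = span_head(ma), span_head(mb)
            # nearest qualifying verb per distinct lemma carries the relation
            nearest: dict[str, tuple[int, int]] = {}
            for tok in sent.tokens:
                t = tok.index
                if t in (ha, hb) or tok.upos != "VERB":
                    continue
                lemma = tok.lemma.lower()
                if lemma not in verbs.lemmas:
                    continue
                dist = steps_to(ha, t)
                if dist is None or steps_to(hb, t) is None:
                    continue
                if lemma not in nearest or dist < nearest[lemma][0]:
                    nearest[lemma] = (dist, t)
            for lemma, (_, t) in nearest.items():
                ra = role(sent.token(verb_child_toward(t, ha)).deprel)
                rb = role(sent.token(verb_child_toward(t, hb)).deprel)
                first, second = sorted((ma, mb), key=lambda m: m.first_token)
                if ra == "cause" and rb != "cause":
                    cause, effect = ma, mb
                elif rb == "cause" and ra != "cause":
                    cause, effect = mb, ma
                else:
                    cause, effect = first, second
                out.add((cause.key, effect.key, lemma))
    return out


class TestOracleEquivalence:
    def test_set_identical_on_1000_random_trees(self):
        rng = random.Random(424242)
        verbs = load_causal_verbs()
        checked_nonempty = 0
        for _ in range(1000):
            sent = random_sentence(rng)
            mentions = random_mentions(rng, sent)
            rels = extract_relations(sent, mentions, verbs)
            got = {(r.cause.key, r.effect.key, r.verb_lemma) for r in rels}
            expected = _oracle_extract(sent, mentions, verbs)
            assert got == expected
            checked_nonempty += bool(expected)
        assert checked_nonempty > 50  # the sample exercises non-trivial cases

    def test_every_relation_verb_is_strict_common_ancestor(self):
        rng = random.Random(77)
        verbs = load_causal_verbs()
        for _ in range(300):
            sent = random_sentence(rng)
            mentions = random_mentions(rng, sent)
            heads = {t.index: t.head for t in sent.tokens}
            for r in extract_relations(sent, mentions, verbs):
                ha = entity_head(sent, r.cause)
                hb = entity_head(sent, r.effect)
                assert r.verb_index not in (ha, hb)
                assert _reaches(heads, ha, r.verb_index)
                assert _reaches(heads, hb, r.verb_index)

    def test_enlarging_verb_set_never_removes_relations(self):
        rng = random.Random(555)
        small = CausalVerbSet(lemmas=frozenset({"induce", "cause"}))
        big = load_causal_verbs()
        assert small.lemmas <= big.lemmas
        for _ in range(300):
            sent = random_sentence(rng)
            mentions = random_mentions(rng, sent)
            rel_small = {(r.cause.key, r.effect.key, r.verb_lemma)
                         for r in extract_relations(sent, mentions, small)}
            rel_big = {(r.cause.key, r.effect.key, r.verb_lemma)
                       for r in extract_relations(sent, mentions, big)}
            assert rel_small <= rel_big

    def test_swapping_mention_order_preserves_orientation(self):
        rng = random.Random(91)
        verbs = load_causal_verbs()
        for _ in range(200):
            sent = random_sentence(rng)
            mentions = random_mentions(rng, sent)
            fwd = {(r.cause.key, r.effect.key, r.verb_lemma)
                   for r in extract_relations(sent, mentions, verbs)}
            rev = {(r.cause.key, r.effect.key, r.verb_lemma)
                   for r in extract_relations(sent, list(reversed(mentions)), verbs)}
            assert fwd == rev
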