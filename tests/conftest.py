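"""Shared fixtures: three hand-parsed sentences covering the active,
passive and coordinated-subject frames, plus a seeded random-tree factory
used by the oracle-equivalence tests."""

from __future__ import annotations

import random

import pytest

from toxkg.entity_recognition import EntityMention
from toxkg.parse_layer import Sentence, Token


def _sentence(sent_id: str, rows: list[tuple]) -> Sentence:
    tokens = [Token(index=i, form=f, lemma=l, upos=u, head=h, deprel=d)
              for i, f, l, u, h, d in rows]
    return Sentence(sent_id=sent_id, doc_id="fixture", tokens=tokens)


@pytest.fixture(scope="session")
def sent_active() -> Sentence:
    """Paracetamol induces steatosis in rats ."""
    return _sentence("f1", [
        (1, "Paracetamol", "paracetamol", "NOUN", 2, "nsubj"),
        (2, "induces", "induce", "VERB", 0, "root"),
        (3, "steatosis", "steatosis", "NOUN", 2, "obj"),
        (4, "in", "in", "ADP", 5, "case"),
        (5, "rats", "rat", "NOUN", 2, "obl"),
        (6, ".", ".", "PUNCT", 2, "punct"),
    ])


@pytest.fixture(scope="session")
def sent_passive() -> Sentence:
    """Steatosis is induced by valproic acid ."""
    return _sentence("f2", [
        (1, "Steatosis", "steatosis", "NOUN", 3, "nsubj:pass"),
        (2, "is", "be", "AUX", 3, "aux:pass"),
        (3, "induced", "induce", "VERB", 0, "root"),
        (4, "by", "by", "ADP", 6, "case"),
        (5, "valproic", "valproic", "ADJ", 6, "amod"),
        (6, "acid", "acid", "NOUN", 3, "obl:agent"),
        (7, ".", ".", "PUNCT", 3, "punct"),
    ])


@pytest.fixture(scope="session")
def sent_coordinated() -> Sentence:
    """Naringin and valproic acid induce cholestasis in rats ."""
    return _sentence("f3", [
        (1, "Naringin", "naringin", "NOUN", 5, "nsubj"),
        (2, "and", "and", "CCONJ", 4, "cc"),
        (3, "valproic", "valproic", "ADJ", 4, "amod"),
        (4, "acid", "acid", "NOUN", 1, "conj"),
        (5, "induce", "induce", "VERB", 0, "root"),
        (6, "cholestasis", "cholestasis", "NOUN", 5, "obj"),
        (7, "in", "in", "ADP", 8, "case"),
        (8, "rats", "rat", "NOUN", 5, "obl"),
        (9, ".", ".", "PUNCT", 5, "punct"),
    ])


def mention(sent: Sentence, first: int, last: int, label: str) -> EntityMention:
    toks = sent.tokens[first - 1:last]
    return EntityMention(
        doc_id=sent.doc_id, sent_id=sent.sent_id,
        first_token=first, last_token=last, label=label,
        surface=" ".join(t.form for t in toks),
        key=" ".join(t.lemma.lower() for t in toks),
    )


# ---------------------------------------------------------------------------
# randomized inputs for oracle tests

UPOS_POOL = ["NOUN", "VERB", "ADJ", "ADP", "ADV"]
DEPREL_POOL = ["nsubj", "obj", "obl", "nmod", "amod", "conj", "advmod",
               "case", "obl:agent", "nsubj:pass", "ccomp"]
VERB_LEMMA_POOL = ["induce", "cause", "trigger", "increase", "inhibit",
                   "study", "measure", "observe", "lead", "associate"]
NOUN_LEMMA_POOL = [f"w{i}" for i in range(20)]


def random_sentence(rng: random.Random, n_min: int = 3, n_max: int = 15) -> Sentence:
    """Random-recursive dependency tree with random tags and lemmas; always
    a valid single-rooted tree, arbitrary head directions."""
    n = rng.randint(n_min, n_max)
    order = rng.sample(range(1, n + 1), n)
    head = {order[0]: 0}
    for i in range(1, n):
        head[order[i]] = rng.choice(order[:i])
    tokens = []
    for idx in range(1, n + 1):
        upos = rng.choice(UPOS_POOL)
        lemma = rng.choice(VERB_LEMMA_POOL if upos == "VERB" else NOUN_LEMMA_POOL)
        deprel = "root" if head[idx] == 0 else rng.choice(DEPREL_POOL)
        tokens.append(Token(index=idx, form=lemma, lemma=lemma, upos=upos,
                            head=head[idx], deprel=deprel))
    return Sentence(sent_id=f"r{rng.randint(0, 10**9)}", doc_id="rand", tokens=tokens)


def random_mentions(rng: random.Random, sent: Sentence,
                    max_mentions: int = 4) -> list[EntityMention]:
    """Random non-overlapping labeled spans over a sentence's tokens."""
    n = len(sent.tokens)
    free = list(range(1, n + 1))
    mentions = []
    for _ in range(rng.randint(0, max_mentions)):
        if not free:
            break
        start = rng.choice(free)
        length = rng.randint(1, 2)
        span = list(range(start, min(start + length, n + 1)))
        if any(i not in free for i in span):
            span = [start]
        for i in span:
            free.remove(i)
        label = rng.choice(["COMPOUND", "PHENOTYPE"])
        mentions.append(mention(sent, span[0], span[-1], label))
    return sorted(mentions, key=lambda m: m.first_token)
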