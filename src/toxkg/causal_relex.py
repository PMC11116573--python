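"""Causal relation extraction over dependency trees.

Two entity mentions in a sentence are considered causally related when a
verb from a configurable causal-verb list (matched by lemma, so
conjugation does not matter) is a strict common ancestor of both mention
heads in the dependency tree.  Relations are sentence-local and oriented
by a UD-role heuristic: the mention attached to the verb through a
subject-like relation (nsubj, csubj, obl:agent) is the cause, the one
attached through an object/oblique-like relation the effect; when the
roles do not disambiguate, linear order decides and the relation is
flagged ``LINEAR_FALLBACK``.

Known, documented behaviors of the rule:

* Coordinated subjects ("A and B induce C") yield one relation per
  conjunct, including protective co-mentions — a recall-oriented false
  positive mode that downstream evaluation can account for.
* The verb must strictly dominate both heads, so participial constructions
  where the effect heads the clause ("steatosis caused by X") are missed.
* Nominal uses of listed lemmas ("an increase in ALT") do not trigger:
  the causal token must carry ``upos == VERB``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from importlib import resources
from typing import IO, Iterable

from .entity_recognition import EntityMention
from .parse_layer import Sentence, ancestors

__all__ = [
    "CausalVerbSet",
    "CausalRelation",
    "SYNTACTIC",
    "LINEAR_FALLBACK",
    "DEFAULT_POLICY",
    "load_causal_verbs",
    "entity_head",
    "common_causal_ancestors",
    "orient",
    "extract_relations",
    "write_relations_tsv",
    "read_relations_tsv",
    "write_relations_jsonl",
]

SYNTACTIC = "SYNTACTIC"
LINEAR_FALLBACK = "LINEAR_FALLBACK"

#: UD relations whose bearer acts as the cause argument of the verb.
CAUSE_ROLES = frozenset({"nsubj", "csubj", "obl:agent"})
#: UD relations whose bearer acts as the effect argument.
EFFECT_ROLES = frozenset({
    "obj", "iobj", "nsubj:pass", "csubj:pass", "obl",
    "ccomp", "xcomp", "advcl", "nmod",
})

#: Label pairs eligible for a relation under the default policy:
#: compound–phenotype and phenotype–phenotype, never compound–compound.
DEFAULT_POLICY = frozenset({
    frozenset({"COMPOUND", "PHENOTYPE"}),
    frozenset({"PHENOTYPE"}),
})


@dataclass(frozen=True)
class CausalVerbSet:
    """Deduplicated set of lowercased causal-verb lemmas."""

    lemmas: frozenset[str]

    def __contains__(self, lemma: str) -> bool:
        return lemma.lower() in self.lemmas

    def __len__(self) -> int:
        return len(self.lemmas)


@dataclass(frozen=True)
class CausalRelation:
    """An oriented (cause, effect, verb lemma) triple with provenance back
    to the exact sentence it was extracted from."""

    cause: EntityMention
    effect: EntityMention
    verb_lemma: str
    verb_index: int
    orientation_method: str
    doc_id: str
    sent_id: str
    sentence_text: str


def load_causal_verbs(config: Iterable[str] | None = None) -> CausalVerbSet:
    """Load the causal-verb set; without a config, the shipped default list.

    Input lemmas are lowercased and deduplicated ("lead" is printed twice
    in the default list; the 23 entries collapse to 22).  Comment lines
    starting with ``#`` and blank lines are ignored.
    """
    if config is None:
        text = resources.files("toxkg.data").joinpath("causal_verbs.txt").read_text()
        config = text.splitlines()
    lemmas = frozenset(
        line.strip().lower()
        for line in config
        if line.strip() and not line.strip().startswith("#")
    )
    if not lemmas:
        raise ValueError("causal verb list must contain at least one lemma")
    return CausalVerbSet(lemmas=lemmas)


def entity_head(sentence: Sentence, mention: EntityMention) -> int:
    """Head token of a mention span: the token whose own head lies outside
    the span (or is the root); the leftmost such token if several qualify."""
    first, last = mention.first_token, mention.last_token
    if not (1 <= first <= last <= len(sentence.tokens)):
        raise ValueError(f"span {mention.span} invalid for sentence {sentence.sent_id!r}")
    for i in range(first, last + 1):
        head = sentence.token(i).head
        if head == 0 or not first <= head <= last:
            return i
    raise AssertionError("valid tree must have a span head")  # pragma: no cover


def common_causal_ancestors(sentence: Sentence, head_a: int, head_b: int,
                            verbs: CausalVerbSet) -> list[int]:
    """Causal verbs strictly dominating both tokens, nearest-to-heads first.

    A token qualifies if it is a VERB, its lemma is in ``verbs``, and it
    appears on both head-to-root chains (so it equals neither head).  The
    common ancestors of two tokens form a chain, returned deepest first.
    """
    chain_a = ancestors(sentence, head_a)
    set_b = set(ancestors(sentence, head_b))
    out = []
    for idx in chain_a:  # nearest first by construction
        if idx in set_b and idx not in (head_a, head_b):
            tok = sentence.token(idx)
            if tok.upos == "VERB" and tok.lemma.lower() in verbs.lemmas:
                out.append(idx)
    return out


def _role_class(deprel: str) -> str | None:
    """Classify a UD relation as cause-like or effect-like; exact label
    first, then its base relation before ':' (parsers differ in subtypes)."""
    for label in (deprel, deprel.split(":")[0]):
        if label in CAUSE_ROLES:
            return "cause"
        if label in EFFECT_ROLES:
            return "effect"
    return None


def _child_on_path(sentence: Sentence, verb_index: int, head: int) -> int:
    """The child of the verb lying on ``head``'s ancestor path (possibly
    ``head`` itself when it attaches directly to the verb)."""
    chain = [head] + ancestors(sentence, head)
    pos = chain.index(verb_index)
    return chain[pos - 1]


def orient(sentence: Sentence, verb_index: int,
           mention_a: EntityMention, mention_b: EntityMention,
           ) -> tuple[EntityMention, EntityMention, str]:
    """Assign cause/effect between two mentions dominated by a causal verb.

    Each mention is represented by the verb's child on its head's ancestor
    path; if exactly one of the two children carries a cause-like relation
    the orientation is ``SYNTACTIC``, otherwise the earlier mention in the
    sentence is taken as cause with ``LINEAR_FALLBACK``.  Symmetric in its
    mention arguments.
    """
    # canonicalize argument order so the result is symmetric
    a, b = sorted((mention_a, mention_b), key=lambda m: m.first_token)
    roles = []
    for m in (a, b):
        child = _child_on_path(sentence, verb_index, entity_head(sentence, m))
        roles.append(_role_class(sentence.token(child).deprel))
    if roles[0] == "cause" and roles[1] != "cause":
        return a, b, SYNTACTIC
    if roles[1] == "cause" and roles[0] != "cause":
        return b, a, SYNTACTIC
    return a, b, LINEAR_FALLBACK


def extract_relations(sentence: Sentence, mentions: list[EntityMention],
                      verbs: CausalVerbSet,
                      policy: frozenset[frozenset[str]] = DEFAULT_POLICY,
                      ) -> list[CausalRelation]:
    """Extract all causal relations among a sentence's entity mentions.

    For every unordered mention pair whose label pair the policy permits
    and whose normalized keys differ, one relation is emitted per distinct
    causal lemma among the common causal ancestors; the nearest verb token
    with that lemma carries the provenance.  Duplicates by
    (cause key, effect key, lemma) are collapsed within the sentence.
    """
    relations: list[CausalRelation] = []
    seen: set[tuple[str, str, str]] = set()
    for i in range(len(mentions)):
        for j in range(i + 1, len(mentions)):
            ma, mb = mentions[i], mentions[j]
            if ma.key == mb.key:
                continue
            if frozenset({ma.label, mb.label}) not in policy:
                continue
            head_a = entity_head(sentence, ma)
            head_b = entity_head(sentence, mb)
            common = common_causal_ancestors(sentence, head_a, head_b, verbs)
            lemma_to_nearest: dict[str, int] = {}
            for idx in common:  # nearest first: first hit per lemma wins
                lemma = sentence.token(idx).lemma.lower()
                lemma_to_nearest.setdefault(lemma, idx)
            for lemma, verb_index in sorted(lemma_to_nearest.items()):
                cause, effect, method = orient(sentence, verb_index, ma, mb)
                sig = (cause.key, effect.key, lemma)
                if sig in seen:
                    continue
                seen.add(sig)
                relations.append(CausalRelation(
                    cause=cause, effect=effect,
                    verb_lemma=lemma, verb_index=verb_index,
                    orientation_method=method,
                    doc_id=sentence.doc_id, sent_id=sentence.sent_id,
                    sentence_text=sentence.text,
                ))
    return relations


_REL_COLS = ("doc_id", "sent_id", "cause_key", "cause_label", "effect_key",
             "effect_label", "verb_lemma", "verb_index", "orientation_method",
             "sentence_text")


def write_relations_tsv(relations: Iterable[CausalRelation], stream: IO[str]) -> None:
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(_REL_COLS)
    for r in relations:
        writer.writerow([r.doc_id, r.sent_id, r.cause.key, r.cause.label,
                         r.effect.key, r.effect.label, r.verb_lemma,
                         r.verb_index, r.orientation_method, r.sentence_text])


def read_relations_tsv(stream: str | IO[str]) -> list[CausalRelation]:
    """Read relations back from TSV; mention spans are not stored in the
    tabular form, so reconstructed mentions carry key/label only."""
    lines = stream.splitlines() if isinstance(stream, str) else stream
    reader = csv.reader(lines, delimiter="\t")
    next(reader, None)
    out = []
    for row in reader:
        if not row:
            continue
        cause = EntityMention(doc_id=row[0], sent_id=row[1], first_token=1,
                              last_token=1, label=row[3], surface=row[2], key=row[2])
        effect = EntityMention(doc_id=row[0], sent_id=row[1], first_token=1,
                               last_token=1, label=row[5], surface=row[4], key=row[4])
        out.append(CausalRelation(
            cause=cause, effect=effect, verb_lemma=row[6],
            verb_index=int(row[7]), orientation_method=row[8],
            doc_id=row[0], sent_id=row[1], sentence_text=row[9],
        ))
    return out


def write_relations_jsonl(relations: Iterable[CausalRelation], stream: IO[str]) -> None:
    for r in relations:
        stream.write(json.dumps({
            "doc_id": r.doc_id, "sent_id": r.sent_id,
            "cause_key": r.cause.key, "cause_label": r.cause.label,
            "effect_key": r.effect.key, "effect_label": r.effect.label,
            "verb_lemma": r.verb_lemma, "verb_index": r.verb_index,
            "orientation_method": r.orientation_method,
            "sentence_text": r.sentence_text,
        }, ensure_ascii=False) + "\n")
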