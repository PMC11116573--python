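"""Synthetic abstracts with gold parses, entities and relations.

The generator is the pipeline's offline test bed: it emits abstracts
composed of templated sentences whose dependency trees are constructed by
hand, so extraction results can be scored against an exact gold standard
without running any parser.  Four templates cover the sentence shapes the
extraction rule must handle:

ACTIVE
    "<compound> induces <phenotype> in rats ."  — one true relation.
PASSIVE
    "<phenotype> is induced by <compound> ."  — one true relation through
    the passive frame (nsubj:pass / obl:agent).
COORDINATED
    "<compound A> and <compound B> induce <phenotype> in rats ."  — the
    conjunct subject (B) carries the true relation; the first subject's
    relation is planted as an *expected false positive*, reproducing the
    known failure mode where a protective co-mentioned compound gets
    lumped in with the causal one.
DISTRACTOR
    "<compound> was measured in patients with <phenotype> ."  — entities
    present, no causal verb, no relation.

Generation is fully deterministic given the seed.  The single random
stream is consumed in a fixed, documented order per sentence — template
choice first, then vocabulary draws, then verb choice — so adding
templates later cannot silently shift existing draws.

What this emulates and what it does not: the corpus exercises entity
matching, tree-based relation extraction, orientation, graph merging and
provenance end-to-end, but the sentences are far simpler than real
abstracts — no negation, hedging, anaphora, parser noise or out-of-lexicon
entities — so perfect scores here bound only the correctness of the
machinery, not recall on real literature.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .causal_relex import CausalRelation
from .corpus_io import Corpus, Document, write_jsonl
from .entity_recognition import EntityMention, Lexicon
from .parse_layer import ParsedDocument, Sentence, Token, write_conllu

__all__ = [
    "TEMPLATES",
    "GeneratorConfig",
    "GoldRelation",
    "GoldStandard",
    "EvaluationResult",
    "generate",
    "evaluate",
    "write_fixture_dir",
]

TEMPLATES = ("ACTIVE", "PASSIVE", "COORDINATED", "DISTRACTOR")

#: lemma -> (3rd-person singular, past participle) for template realization
_VERB_FORMS = {
    "induce": ("induces", "induced"),
    "cause": ("causes", "caused"),
    "trigger": ("triggers", "triggered"),
    "produce": ("produces", "produced"),
    "elevate": ("elevates", "elevated"),
    "generate": ("generates", "generated"),
}

_DEFAULT_COMPOUNDS = (
    "paracetamol", "valproic acid", "tributyltin", "naringin",
    "tebuconazole", "chloroethanol", "fialuridine", "amiodarone",
)
_DEFAULT_PHENOTYPES = (
    "steatosis", "cholestasis", "liver injury", "bile accumulation",
    "oxidative stress", "hepatotoxicity", "lipid accumulation", "fibrosis",
)


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic corpus.

    Defaults: 200 abstracts of 3–6 sentences drawn from small disjoint
    compound/phenotype vocabularies, with all four templates active
    (weights 0.35 / 0.25 / 0.15 / 0.25), seed 7.
    """

    n_docs: int = 200
    sentences_per_doc: tuple[int, int] = (3, 6)
    compound_vocab: tuple[str, ...] = _DEFAULT_COMPOUNDS
    phenotype_vocab: tuple[str, ...] = _DEFAULT_PHENOTYPES
    template_weights: dict[str, float] = field(default_factory=lambda: {
        "ACTIVE": 0.35, "PASSIVE": 0.25, "COORDINATED": 0.15, "DISTRACTOR": 0.25,
    })
    seed: int = 7

    def validate(self) -> None:
        if self.n_docs < 1:
            raise ValueError("n_docs must be >= 1")
        lo, hi = self.sentences_per_doc
        if not 1 <= lo <= hi:
            raise ValueError(f"invalid sentences_per_doc range {self.sentences_per_doc}")
        if not self.compound_vocab or not self.phenotype_vocab:
            raise ValueError("vocabularies must be non-empty")
        if set(self.compound_vocab) & set(self.phenotype_vocab):
            raise ValueError("compound and phenotype vocabularies must be disjoint")
        unknown = set(self.template_weights) - set(TEMPLATES)
        if unknown:
            raise ValueError(f"unknown template(s): {sorted(unknown)}")
        if any(w < 0 for w in self.template_weights.values()):
            raise ValueError("template weights must be >= 0")
        if sum(self.template_weights.values()) <= 0:
            raise ValueError("template weights must sum to > 0")

    def lexicon(self) -> Lexicon:
        """The generating vocabularies as an entity lexicon."""
        lex = Lexicon()
        for phrase in self.compound_vocab:
            lex.add(phrase, "COMPOUND")
        for phrase in self.phenotype_vocab:
            lex.add(phrase, "PHENOTYPE")
        return lex


@dataclass(frozen=True)
class GoldRelation:
    cause_key: str
    effect_key: str
    verb_lemma: str
    doc_id: str
    sent_id: str


@dataclass
class GoldStandard:
    """Planted truth for one generated corpus."""

    entities: list[EntityMention] = field(default_factory=list)
    relations: list[GoldRelation] = field(default_factory=list)
    expected_false_positives: list[GoldRelation] = field(default_factory=list)


# ---------------------------------------------------------------------------
# template realization


def _phrase_tokens(phrase: str, start: int, head: int, deprel: str,
                   capitalize: bool) -> list[Token]:
    """Tokens of a noun phrase: modifiers attach to the last word, which
    attaches to ``head`` with ``deprel``."""
    words = phrase.split()
    last = start + len(words) - 1
    toks = []
    for offset, word in enumerate(words):
        form = word[0].upper() + word[1:] if capitalize and offset == 0 else word
        idx = start + offset
        if idx == last:
            toks.append(Token(idx, form, word.lower(), "NOUN", head, deprel))
        else:
            toks.append(Token(idx, form, word.lower(), "ADJ", last, "amod"))
    return toks


def _mention(sent: Sentence, first: int, last: int, label: str) -> EntityMention:
    toks = sent.tokens[first - 1:last]
    return EntityMention(
        doc_id=sent.doc_id, sent_id=sent.sent_id,
        first_token=first, last_token=last, label=label,
        surface=" ".join(t.form for t in toks),
        key=" ".join(t.lemma for t in toks),
    )


def _active(sent_id: str, doc_id: str, compound: str, phenotype: str,
            lemma: str) -> tuple[Sentence, list[tuple[int, int, str]], list[tuple[str, str, str]]]:
    c = len(compound.split())
    p = len(phenotype.split())
    v = c + 1
    toks = _phrase_tokens(compound, 1, v, "nsubj", capitalize=True)
    toks.append(Token(v, _VERB_FORMS[lemma][0], lemma, "VERB", 0, "root"))
    toks += _phrase_tokens(phenotype, v + 1, v, "obj", capitalize=False)
    rats = v + p + 2
    toks.append(Token(v + p + 1, "in", "in", "ADP", rats, "case"))
    toks.append(Token(rats, "rats", "rat", "NOUN", v, "obl"))
    toks.append(Token(rats + 1, ".", ".", "PUNCT", v, "punct"))
    sent = Sentence(sent_id=sent_id, doc_id=doc_id, tokens=toks)
    spans = [(1, c, "COMPOUND"), (v + 1, v + p, "PHENOTYPE")]
    gold = [(compound, phenotype, lemma)]
    return sent, spans, gold


def _passive(sent_id: str, doc_id: str, compound: str, phenotype: str,
             lemma: str):
    c = len(compound.split())
    p = len(phenotype.split())
    v = p + 2
    toks = _phrase_tokens(phenotype, 1, v, "nsubj:pass", capitalize=True)
    toks.append(Token(p + 1, "is", "be", "AUX", v, "aux:pass"))
    toks.append(Token(v, _VERB_FORMS[lemma][1], lemma, "VERB", 0, "root"))
    last_c = v + 1 + c
    toks.append(Token(v + 1, "by", "by", "ADP", last_c, "case"))
    toks += _phrase_tokens(compound, v + 2, v, "obl:agent", capitalize=False)
    toks.append(Token(last_c + 1, ".", ".", "PUNCT", v, "punct"))
    sent = Sentence(sent_id=sent_id, doc_id=doc_id, tokens=toks)
    spans = [(1, p, "PHENOTYPE"), (v + 2, last_c, "COMPOUND")]
    gold = [(compound, phenotype, lemma)]
    return sent, spans, gold


def _coordinated(sent_id: str, doc_id: str, compound_fp: str, compound_true: str,
                 phenotype: str, lemma: str):
    """Coordinated subjects; the second (conjunct) subject carries the true
    relation, the first is planted as the expected false positive."""
    a = len(compound_fp.split())
    b = len(compound_true.split())
    p = len(phenotype.split())
    last_b = a + 1 + b
    v = last_b + 1
    toks = _phrase_tokens(compound_fp, 1, v, "nsubj", capitalize=True)
    toks.append(Token(a + 1, "and", "and", "CCONJ", last_b, "cc"))
    toks += _phrase_tokens(compound_true, a + 2, a, "conj", capitalize=False)
    # plural agreement: the bare lemma serves as the plural present form
    toks.append(Token(v, lemma, lemma, "VERB", 0, "root"))
    toks += _phrase_tokens(phenotype, v + 1, v, "obj", capitalize=False)
    rats = v + p + 2
    toks.append(Token(v + p + 1, "in", "in", "ADP", rats, "case"))
    toks.append(Token(rats, "rats", "rat", "NOUN", v, "obl"))
    toks.append(Token(rats + 1, ".", ".", "PUNCT", v, "punct"))
    sent = Sentence(sent_id=sent_id, doc_id=doc_id, tokens=toks)
    spans = [(1, a, "COMPOUND"), (a + 2, last_b, "COMPOUND"),
             (v + 1, v + p, "PHENOTYPE")]
    gold = [(compound_true, phenotype, lemma)]
    expected_fp = [(compound_fp, phenotype, lemma)]
    return sent, spans, gold, expected_fp


def _distractor(sent_id: str, doc_id: str, compound: str, phenotype: str):
    c = len(compound.split())
    v = c + 2
    toks = _phrase_tokens(compound, 1, v, "nsubj:pass", capitalize=True)
    toks.append(Token(c + 1, "was", "be", "AUX", v, "aux:pass"))
    toks.append(Token(v, "measured", "measure", "VERB", 0, "root"))
    patients = v + 2
    toks.append(Token(v + 1, "in", "in", "ADP", patients, "case"))
    toks.append(Token(patients, "patients", "patient", "NOUN", v, "obl"))
    p = len(phenotype.split())
    last_p = patients + 1 + p
    toks.append(Token(patients + 1, "with", "with", "ADP", last_p, "case"))
    toks += _phrase_tokens(phenotype, patients + 2, patients, "nmod", capitalize=False)
    toks.append(Token(last_p + 1, ".", ".", "PUNCT", v, "punct"))
    sent = Sentence(sent_id=sent_id, doc_id=doc_id, tokens=toks)
    spans = [(1, c, "COMPOUND"), (patients + 2, last_p, "PHENOTYPE")]
    return sent, spans


def generate(config: GeneratorConfig) -> tuple[Corpus, list[ParsedDocument], GoldStandard]:
    """Generate a corpus, its gold parses, and the planted gold standard.

    Deterministic given ``config.seed``; per sentence the random stream is
    consumed as template choice → vocabulary draw(s) → verb choice.
    """
    config.validate()
    rng = random.Random(config.seed)
    names = [t for t in TEMPLATES if config.template_weights.get(t, 0) > 0]
    weights = [config.template_weights[t] for t in names]
    verb_lemmas = sorted(_VERB_FORMS)

    docs: list[Document] = []
    parsed: list[ParsedDocument] = []
    gold = GoldStandard()

    for d in range(1, config.n_docs + 1):
        doc_id = f"synth-{d:04d}"
        n_sents = rng.randint(*config.sentences_per_doc)
        pdoc = ParsedDocument(doc_id=doc_id)
        for s in range(1, n_sents + 1):
            sent_id = f"{doc_id}-s{s}"
            template = rng.choices(names, weights=weights)[0]
            if template == "ACTIVE":
                compound = rng.choice(config.compound_vocab)
                phenotype = rng.choice(config.phenotype_vocab)
                lemma = rng.choice(verb_lemmas)
                sent, spans, rels = _active(sent_id, doc_id, compound, phenotype, lemma)
                fps = []
            elif template == "PASSIVE":
                compound = rng.choice(config.compound_vocab)
                phenotype = rng.choice(config.phenotype_vocab)
                lemma = rng.choice(verb_lemmas)
                sent, spans, rels = _passive(sent_id, doc_id, compound, phenotype, lemma)
                fps = []
            elif template == "COORDINATED":
                if len(config.compound_vocab) < 2:
                    raise ValueError("COORDINATED template needs >= 2 compounds")
                c_fp, c_true = rng.sample(list(config.compound_vocab), 2)
                phenotype = rng.choice(config.phenotype_vocab)
                lemma = rng.choice(verb_lemmas)
                sent, spans, rels, fps = _coordinated(
                    sent_id, doc_id, c_fp, c_true, phenotype, lemma)
            else:  # DISTRACTOR
                compound = rng.choice(config.compound_vocab)
                phenotype = rng.choice(config.phenotype_vocab)
                sent, spans = _distractor(sent_id, doc_id, compound, phenotype)
                rels, fps = [], []
            pdoc.sentences.append(sent)
            for first, last, label in spans:
                gold.entities.append(_mention(sent, first, last, label))
            for cause, effect, lemma_ in rels:
                gold.relations.append(GoldRelation(cause, effect, lemma_, doc_id, sent_id))
            for cause, effect, lemma_ in fps:
                gold.expected_false_positives.append(
                    GoldRelation(cause, effect, lemma_, doc_id, sent_id))
        abstract = " ".join(s.text for s in pdoc.sentences)
        docs.append(Document(doc_id=doc_id, title=f"Synthetic abstract {d}",
                             abstract=abstract, compound_query=""))
        parsed.append(pdoc)

    corpus = Corpus(documents=docs, provenance=f"synthetic(seed={config.seed})")
    return corpus, parsed, gold


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvaluationResult:
    precision: float
    recall: float
    f1: float
    true_positives: int
    false_positives: int
    false_negatives: int
    known_false_positives: int
    empty_prediction_convention: bool = False

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.precision, self.recall, self.f1)


def _rel_key(doc_id: str, sent_id: str, cause: str, effect: str, verb: str,
             match_on: str) -> tuple:
    if match_on == "TRIPLE":
        return (doc_id, sent_id, cause, effect, verb)
    return (doc_id, sent_id, cause, effect)


def evaluate(predicted: list[CausalRelation], gold: GoldStandard,
             match_on: str = "PAIR", forgive_known: bool = False) -> EvaluationResult:
    """Precision/recall/F1 of predicted relations against the gold standard.

    ``PAIR`` matches on (cause key, effect key) per document-sentence;
    ``TRIPLE`` additionally requires the verb lemma.  Planted expected
    false positives are counted separately; with ``forgive_known`` they are
    excluded from the false-positive count.  An empty prediction set scores
    precision 1.0 by convention (flagged in the result).
    """
    if match_on not in {"PAIR", "TRIPLE"}:
        raise ValueError(f"match_on must be PAIR or TRIPLE, got {match_on!r}")
    gold_keys = {_rel_key(g.doc_id, g.sent_id, g.cause_key, g.effect_key,
                          g.verb_lemma, match_on) for g in gold.relations}
    known_fp_keys = {_rel_key(g.doc_id, g.sent_id, g.cause_key, g.effect_key,
                              g.verb_lemma, match_on)
                     for g in gold.expected_false_positives}
    pred_keys = {_rel_key(r.doc_id, r.sent_id, r.cause.key, r.effect.key,
                          r.verb_lemma, match_on) for r in predicted}

    tp = len(pred_keys & gold_keys)
    fp_keys = pred_keys - gold_keys
    known = len(fp_keys & known_fp_keys)
    fp = len(fp_keys) - known if forgive_known else len(fp_keys)
    fn = len(gold_keys - pred_keys)

    empty = not pred_keys
    precision = 1.0 if (tp + fp) == 0 else tp / (tp + fp)
    recall = 1.0 if not gold_keys else tp / len(gold_keys)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return EvaluationResult(
        precision=precision, recall=recall, f1=f1,
        true_positives=tp, false_positives=fp, false_negatives=fn,
        known_false_positives=known,
        empty_prediction_convention=empty,
    )


def write_fixture_dir(config: GeneratorConfig, out_dir: str | Path) -> dict[str, Path]:
    """Emit the generated corpus as plain-text fixture files:
    corpus.jsonl, gold.conllu, gold_entities.tsv, gold_relations.tsv,
    expected_fp.tsv and lexicon.tsv."""
    from .entity_recognition import write_mentions_tsv

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    corpus, parsed, gold = generate(config)
    paths = {name: out_dir / name for name in (
        "corpus.jsonl", "gold.conllu", "gold_entities.tsv",
        "gold_relations.tsv", "expected_fp.tsv", "lexicon.tsv")}

    with paths["corpus.jsonl"].open("w", encoding="utf-8") as fh:
        write_jsonl(corpus, fh)
    blocks = [f"# newdoc id = {pdoc.doc_id}\n" + write_conllu(pdoc.sentences)
              for pdoc in parsed]
    paths["gold.conllu"].write_text("\n".join(blocks), encoding="utf-8")
    with paths["gold_entities.tsv"].open("w", encoding="utf-8") as fh:
        write_mentions_tsv(gold.entities, fh)
    header = "doc_id\tsent_id\tcause_key\teffect_key\tverb_lemma\n"
    for name, rels in (("gold_relations.tsv", gold.relations),
                       ("expected_fp.tsv", gold.expected_false_positives)):
        with paths[name].open("w", encoding="utf-8") as fh:
            fh.write(header)
            for g in rels:
                fh.write(f"{g.doc_id}\t{g.sent_id}\t{g.cause_key}\t{g.effect_key}\t{g.verb_lemma}\n")
    with paths["lexicon.tsv"].open("w", encoding="utf-8") as fh:
        fh.write("phrase\tlabel\tcanonical\n")
        for phrase in sorted(config.compound_vocab):
            fh.write(f"{phrase}\tCOMPOUND\t{phrase}\n")
        for phrase in sorted(config.phenotype_vocab):
            fh.write(f"{phrase}\tPHENOTYPE\t{phrase}\n")
    return paths
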