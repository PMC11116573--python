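"""Dependency-parsed sentences and CoNLL-U interchange.

The extraction pipeline never parses raw text itself: any external parser
(spaCy, UDPipe, Stanza, ...) can be plugged in as long as it delivers
Universal Dependencies v2 trees, either through the :class:`ParserPlugin`
protocol or as CoNLL-U files read by :func:`read_conllu`.  Every sentence is
validated to be a single-rooted tree before downstream modules touch it.

Token indices are 1-based (the CoNLL-U convention); ``head == 0`` marks the
root.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Protocol

__all__ = [
    "Token",
    "Sentence",
    "ParsedDocument",
    "ParserPlugin",
    "ValidationReport",
    "ConlluParseError",
    "TreeValidationError",
    "read_conllu",
    "write_conllu",
    "validate_tree",
    "ancestors",
]

#: Universal Dependencies v2 part-of-speech inventory.
UD_UPOS = frozenset(
    "ADJ ADP ADV AUX CCONJ DET INTJ NOUN NUM PART PRON PROPN PUNCT SCONJ SYM VERB X".split()
)


class ConlluParseError(ValueError):
    """Malformed CoNLL-U input; message carries the 1-based line number."""


class TreeValidationError(ValueError):
    """A sentence whose head assignments do not form a valid tree."""


@dataclass(frozen=True)
class Token:
    """One syntactic word of a dependency tree.

    ``index`` is the 1-based CoNLL-U ID, ``head`` the index of the governing
    token (0 for the root) and ``deprel`` the UD relation label, with
    subtypes such as ``nsubj:pass`` kept verbatim.
    """

    index: int
    form: str
    lemma: str
    upos: str
    head: int
    deprel: str


@dataclass
class Sentence:
    """A dependency-parsed sentence: contiguous 1..n tokens, one root."""

    sent_id: str
    doc_id: str
    tokens: list[Token]

    @property
    def text(self) -> str:
        """Surface string reconstructed by space-joining token forms."""
        return " ".join(t.form for t in self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)

    def token(self, index: int) -> Token:
        """Return the token with 1-based ``index``."""
        if not 1 <= index <= len(self.tokens):
            raise ValueError(
                f"token index {index} out of range 1..{len(self.tokens)} "
                f"in sentence {self.sent_id!r}"
            )
        return self.tokens[index - 1]


@dataclass
class ParsedDocument:
    """All parsed sentences of one abstract, in document order."""

    doc_id: str
    sentences: list[Sentence] = field(default_factory=list)


class ParserPlugin(Protocol):
    """Contract for an external dependency parser.

    Implementations map a raw document (id, title, abstract) to a
    :class:`ParsedDocument` whose sentences pass :func:`validate_tree`.
    The shipped test-bed uses pre-built trees instead, so no trained model
    is ever required offline.
    """

    def parse(self, doc_id: str, text: str) -> ParsedDocument:  # pragma: no cover
        ...


@dataclass
class ValidationReport:
    """Outcome of structural validation; empty ``violations`` means valid."""

    sent_id: str
    violations: list[str] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.violations


def validate_tree(sentence: Sentence) -> ValidationReport:
    """Check that a sentence's head assignments form a single-rooted tree.

    Reports *all* violations rather than stopping at the first: wrong root
    count, out-of-range heads, self-loops, non-contiguous indices, and
    cycles found by walking each token's head chain with a visited set.
    Never raises.
    """
    report = ValidationReport(sent_id=sentence.sent_id)
    n = len(sentence.tokens)
    if n == 0:
        report.violations.append("empty sentence")
        return report

    indices = [t.index for t in sentence.tokens]
    if indices != list(range(1, n + 1)):
        report.violations.append(f"token indices not contiguous 1..{n}: {indices}")
        return report  # head-chain walking is unsafe on bad indices

    heads = {t.index: t.head for t in sentence.tokens}
    roots = [i for i, h in heads.items() if h == 0]
    if len(roots) == 0:
        report.violations.append("no root token (head=0)")
    elif len(roots) > 1:
        report.violations.append(f"multiple root tokens: {roots}")

    for i, h in heads.items():
        if h == i:
            report.violations.append(f"token {i} is its own head")
        elif not 0 <= h <= n:
            report.violations.append(f"token {i} head {h} out of range 0..{n}")

    if any("out of range" in v or "own head" in v for v in report.violations):
        return report

    for start in heads:
        seen = set()
        cur = start
        while cur != 0:
            if cur in seen:
                cycle = sorted(seen)
                report.violations.append(f"cycle through tokens {cycle}")
                return report
            seen.add(cur)
            cur = heads[cur]
    return report


def ancestors(sentence: Sentence, index: int) -> list[int]:
    """Head chain of a token, nearest ancestor first, root last.

    Excludes the token itself; the root token has no ancestors.  The
    sentence must be a valid tree (guaranteed by :func:`read_conllu`).
    """
    n = len(sentence.tokens)
    if not 1 <= index <= n:
        raise ValueError(f"token index {index} out of range 1..{n}")
    heads = {t.index: t.head for t in sentence.tokens}
    chain: list[int] = []
    cur = heads[index]
    while cur != 0:
        chain.append(cur)
        cur = heads[cur]
    return chain


# ---------------------------------------------------------------------------
# CoNLL-U reading / writing


def _parse_token_line(line: str, lineno: int) -> Token | None:
    cols = line.split("\t")
    if len(cols) != 10:
        raise ConlluParseError(
            f"line {lineno}: expected 10 tab-separated columns, got {len(cols)}"
        )
    tok_id = cols[0]
    if "-" in tok_id or "." in tok_id:
        return None  # multiword-token range or empty node: skipped
    try:
        index = int(tok_id)
    except ValueError as exc:
        raise ConlluParseError(f"line {lineno}: non-integer token ID {tok_id!r}") from exc
    try:
        head = int(cols[6])
    except ValueError as exc:
        raise ConlluParseError(f"line {lineno}: non-integer HEAD {cols[6]!r}") from exc
    upos = cols[3] if cols[3] in UD_UPOS else "X"
    lemma = cols[2] if cols[2] != "_" else cols[1].lower()
    return Token(index=index, form=cols[1], lemma=lemma, upos=upos, head=head, deprel=cols[7])


def read_conllu(stream: str | Iterable[str]) -> list[Sentence]:
    """Read UD v2 CoNLL-U text into validated :class:`Sentence` objects.

    ``sent_id`` / ``doc_id`` are taken from ``# sent_id`` and ``# doc_id``
    (or ``# newdoc id``) comments when present, else synthesized as ``s1``,
    ``s2``, ... within the current document.  Multiword-token and empty-node
    lines are skipped.  Raises :class:`ConlluParseError` with a line number
    on malformed input and :class:`TreeValidationError` naming the sentence
    on structural violations.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in stream]

    sentences: list[Sentence] = []
    tokens: list[Token] = []
    meta: dict[str, str] = {}
    doc_id = ""
    auto_count = 0

    def flush(lineno: int) -> None:
        nonlocal tokens, meta, auto_count
        if not tokens:
            meta = {}
            return
        auto_count += 1
        sid = meta.get("sent_id", f"s{auto_count}")
        did = meta.get("doc_id", doc_id)
        sent = Sentence(sent_id=sid, doc_id=did, tokens=tokens)
        report = validate_tree(sent)
        if not report.is_valid:
            raise TreeValidationError(
                f"sentence {sid!r} (near line {lineno}): " + "; ".join(report.violations)
            )
        sentences.append(sent)
        tokens = []
        meta = {}

    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\r")
        if not line.strip():
            flush(lineno)
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                key = key.strip()
                if key == "newdoc id":
                    doc_id = value.strip()
                    auto_count = 0
                else:
                    meta[key] = value.strip()
            continue
        tok = _parse_token_line(line, lineno)
        if tok is not None:
            tokens.append(tok)
    flush(len(lines) + 1)
    return sentences


def write_conllu(sentences: Iterable[Sentence]) -> str:
    """Serialize sentences in a canonical, byte-deterministic CoNLL-U form.

    Unused columns are written as ``_``; metadata comments are emitted in a
    fixed order (``# doc_id``, ``# sent_id``, ``# text``) so that
    ``write_conllu(read_conllu(x))`` is a fixed point.
    """
    blocks: list[str] = []
    for sent in sentences:
        lines = []
        if sent.doc_id:
            lines.append(f"# doc_id = {sent.doc_id}")
        lines.append(f"# sent_id = {sent.sent_id}")
        lines.append(f"# text = {sent.text}")
        for t in sent.tokens:
            lines.append(
                "\t".join(
                    [str(t.index), t.form, t.lemma, t.upos, "_", "_", str(t.head), t.deprel, "_", "_"]
                )
            )
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + ("\n" if blocks else "")
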