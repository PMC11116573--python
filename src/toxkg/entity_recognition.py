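"""Lexicon-based recognition of COMPOUND and PHENOTYPE mentions.

A deterministic gazetteer matcher stands in for a trained statistical
recognizer: phrases are matched greedily left-to-right over lowercased
token forms, with a lemma fallback, and nested candidates are resolved
longest-span-first (so "valproic acid sodium salt" beats the embedded
"valproic acid").  Statistical recognizers can be plugged in through
:class:`RecognizerPlugin` and their character-offset spans converted with
:func:`char_span_to_token_span`.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Protocol

from .parse_layer import Sentence

logger = logging.getLogger(__name__)

__all__ = [
    "LABELS",
    "Lexicon",
    "EntityMention",
    "RecognizerPlugin",
    "load_lexicon",
    "match_entities",
    "normalize_mention",
    "char_span_to_token_span",
    "write_mentions_tsv",
    "read_mentions_tsv",
]

#: The two-entity inventory: chemical compounds/substances and biological
#: events at any level of organization (molecular to organism).
LABELS = ("COMPOUND", "PHENOTYPE")


@dataclass
class Lexicon:
    """Phrase gazetteer: lowercased token sequence -> (label, canonical key)."""

    entries: dict[tuple[str, ...], tuple[str, str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def add(self, phrase: str, label: str, canonical: str | None = None) -> None:
        words = tuple(phrase.lower().split())
        if not words:
            raise ValueError("empty phrase")
        if label not in LABELS:
            raise ValueError(f"unknown label {label!r}; expected one of {LABELS}")
        canonical = canonical or " ".join(words)
        if words in self.entries:
            old_label, _ = self.entries[words]
            if old_label != label:
                raise ValueError(
                    f"phrase {' '.join(words)!r} already loaded with label {old_label}, "
                    f"conflicting label {label}"
                )
            return  # duplicate, first canonical wins
        self.entries[words] = (label, canonical)

    @property
    def max_len(self) -> int:
        return max((len(w) for w in self.entries), default=0)


@dataclass(frozen=True)
class EntityMention:
    """A labeled token span: [first_token, last_token], 1-based inclusive."""

    doc_id: str
    sent_id: str
    first_token: int
    last_token: int
    label: str
    surface: str
    key: str

    @property
    def span(self) -> tuple[int, int]:
        return (self.first_token, self.last_token)


class RecognizerPlugin(Protocol):
    """Contract for swappable (e.g. statistical) recognizers: yield
    (char_start, char_end, label) spans over the sentence's surface text."""

    def recognize(self, sentence: Sentence) -> Iterable[tuple[int, int, str]]:  # pragma: no cover
        ...


def load_lexicon(stream: str | IO[str]) -> Lexicon:
    """Load a lexicon from TSV with columns phrase, label[, canonical].

    A header row naming the columns is optional.  Extra columns (e.g. a
    curator-supplied ``level``) are accepted and ignored.  Unknown labels
    and conflicting duplicate phrases raise ``ValueError`` naming the line.
    """
    lines = stream.splitlines() if isinstance(stream, str) else stream
    lexicon = Lexicon()
    for lineno, row in enumerate(csv.reader(lines, delimiter="\t"), start=1):
        if not row or not row[0].strip():
            continue
        if lineno == 1 and row[0].strip().lower() == "phrase":
            continue
        if len(row) < 2:
            raise ValueError(f"lexicon line {lineno}: expected phrase<TAB>label")
        phrase, label = row[0].strip(), row[1].strip()
        canonical = row[2].strip() if len(row) > 2 and row[2].strip() else None
        try:
            lexicon.add(phrase, label, canonical)
        except ValueError as exc:
            raise ValueError(f"lexicon line {lineno}: {exc}") from exc
    return lexicon


def _candidates(sentence: Sentence, lexicon: Lexicon) -> list[tuple[int, int]]:
    """All token windows matching a lexicon phrase on all forms or all lemmas."""
    forms = [t.form.lower() for t in sentence.tokens]
    lemmas = [t.lemma.lower() for t in sentence.tokens]
    n = len(forms)
    out = []
    for start in range(n):
        for length in range(1, min(lexicon.max_len, n - start) + 1):
            window_forms = tuple(forms[start:start + length])
            window_lemmas = tuple(lemmas[start:start + length])
            if window_forms in lexicon.entries or window_lemmas in lexicon.entries:
                out.append((start + 1, start + length))
    return out


def match_entities(sentence: Sentence, lexicon: Lexicon) -> list[EntityMention]:
    """Match lexicon phrases in a sentence; returns non-overlapping mentions
    sorted by first token.

    Matching is case-insensitive over token forms, with a fallback to
    lemmas (a phrase matches if either all its forms or all its lemmas
    match).  Overlaps are resolved longest-span-first, ties leftmost;
    matched tokens are consumed.
    """
    chosen: list[tuple[int, int]] = []
    taken: set[int] = set()
    # longest first, then leftmost
    for first, last in sorted(_candidates(sentence, lexicon),
                              key=lambda s: (-(s[1] - s[0]), s[0])):
        if any(i in taken for i in range(first, last + 1)):
            continue
        chosen.append((first, last))
        taken.update(range(first, last + 1))

    mentions = []
    for first, last in sorted(chosen):
        toks = sentence.tokens[first - 1:last]
        window_forms = tuple(t.form.lower() for t in toks)
        window_lemmas = tuple(t.lemma.lower() for t in toks)
        entry = lexicon.entries.get(window_forms) or lexicon.entries[window_lemmas]
        label, _canonical = entry
        surface = " ".join(t.form for t in toks)
        key = " ".join(t.lemma.lower() for t in toks)
        mentions.append(EntityMention(
            doc_id=sentence.doc_id, sent_id=sentence.sent_id,
            first_token=first, last_token=last,
            label=label, surface=surface, key=key,
        ))
    return mentions


def normalize_mention(mention: EntityMention,
                      synonyms: Mapping[str, str] | None = None) -> str:
    """Normalized node key of a mention.

    Default: the lowercased space-joined lemmas of the span.  If a synonym
    table maps that key, the canonical target is returned; without a table,
    distinct phrasings ("hepatic steatosis" vs "liver steatosis") remain
    distinct nodes.
    """
    key = mention.key
    if synonyms and key in synonyms:
        return synonyms[key]
    return key


def char_span_to_token_span(sentence: Sentence, start: int, end: int) -> tuple[int, int] | None:
    """Convert a 0-based half-open character span over ``sentence.text`` to
    a 1-based inclusive token span by maximal token coverage.

    Spans that begin or end inside a token are rejected with a warning and
    ``None`` is returned (partial-token overlap cannot be represented).
    """
    offsets = []
    pos = 0
    for t in sentence.tokens:
        offsets.append((pos, pos + len(t.form)))
        pos += len(t.form) + 1  # single-space joining
    covered = [i + 1 for i, (s, e) in enumerate(offsets) if s >= start and e <= end]
    touched = [i + 1 for i, (s, e) in enumerate(offsets) if s < end and e > start]
    if not covered or covered != touched:
        logger.warning("char span (%d,%d) partially overlaps tokens in %s; rejected",
                       start, end, sentence.sent_id)
        return None
    return (covered[0], covered[-1])


_MENTION_COLS = ("doc_id", "sent_id", "first", "last", "label", "surface", "key")


def write_mentions_tsv(mentions: Iterable[EntityMention], stream: IO[str]) -> None:
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(_MENTION_COLS)
    for m in mentions:
        writer.writerow([m.doc_id, m.sent_id, m.first_token, m.last_token,
                         m.label, m.surface, m.key])


def read_mentions_tsv(stream: str | IO[str]) -> list[EntityMention]:
    lines = stream.splitlines() if isinstance(stream, str) else stream
    reader = csv.reader(lines, delimiter="\t")
    header = next(reader, None)
    if header is None:
        return []
    out = []
    for row in reader:
        if not row:
            continue
        out.append(EntityMention(
            doc_id=row[0], sent_id=row[1],
            first_token=int(row[2]), last_token=int(row[3]),
            label=row[4], surface=row[5], key=row[6],
        ))
    return out
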