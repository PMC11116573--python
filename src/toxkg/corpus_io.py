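"""Abstract ingestion: PubMed queries, MEDLINE XML, JSONL corpora.

A corpus is an ordered, de-duplicated collection of abstracts.  Retrieval
follows the screening protocol used throughout the pipeline: one fixed
PubMed query per compound, at most the first 100 abstracts per compound,
duplicates removed by PMID and by normalized abstract text.  Live
E-utilities fetching is available through the CLI (network required); the
offline entry points here consume saved efetch XML or JSONL.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable

from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "Document",
    "Corpus",
    "build_pubmed_query",
    "read_medline_xml",
    "read_jsonl",
    "write_jsonl",
    "dedupe",
    "cap_per_query",
]

#: Fixed query clause appended to every compound name: abstracts about
#: toxicity in humans or laboratory-animal / disease models.
QUERY_CLAUSE = "toxic* AND (human OR Animals, Laboratory OR Disease Models, Animal)"

DEFAULT_ABSTRACT_CAP = 100


@dataclass(frozen=True)
class Document:
    """One abstract: PMID (or synthetic id), title, abstract text, and the
    compound query that retrieved it (may be empty for hand-built corpora)."""

    doc_id: str
    title: str
    abstract: str
    compound_query: str = ""


@dataclass
class Corpus:
    """Ordered collection of documents plus a provenance descriptor
    (source file path or query string)."""

    documents: list[Document] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)


def build_pubmed_query(compound_name: str) -> str:
    """Build the per-compound PubMed query string.

    The compound name is followed by the fixed toxicity/species clause;
    multiword names are wrapped in double quotes to preserve phrase
    semantics.  Pure and idempotent.
    """
    name = compound_name.strip()
    if not name:
        raise ValueError("compound name must be non-empty")
    if any(ch.isspace() for ch in name) and not (name.startswith('"') and name.endswith('"')):
        name = f'"{name}"'
    return f"{name} AND {QUERY_CLAUSE}"


def _article_abstract(article: etree._Element) -> str:
    # Multi-part structured abstracts are concatenated with single spaces
    # in document order.
    parts = []
    for node in article.findall(".//Abstract/AbstractText"):
        text = "".join(node.itertext()).strip()
        if text:
            parts.append(text)
    return " ".join(parts)


def read_medline_xml(stream: bytes | IO[bytes], compound_query: str = "") -> Corpus:
    """Read a PubMed efetch ``PubmedArticleSet`` into a :class:`Corpus`.

    One document per ``PubmedArticle`` that has a non-empty abstract;
    articles without abstracts are skipped and counted in the log.  Zero
    articles yields an empty corpus, not an error.  Malformed XML raises
    ``ValueError`` naming the reported position.
    """
    data = stream if isinstance(stream, bytes) else stream.read()
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed MEDLINE XML: {exc}") from exc

    docs: list[Document] = []
    skipped = 0
    for article in root.iter("PubmedArticle"):
        pmid_node = article.find(".//PMID")
        pmid = pmid_node.text.strip() if pmid_node is not None and pmid_node.text else ""
        title_node = article.find(".//ArticleTitle")
        title = "".join(title_node.itertext()).strip() if title_node is not None else ""
        abstract = _article_abstract(article)
        if not pmid or not abstract:
            skipped += 1
            continue
        docs.append(Document(doc_id=pmid, title=title, abstract=abstract,
                             compound_query=compound_query))
    if skipped:
        logger.info("read_medline_xml: skipped %d article(s) without PMID/abstract", skipped)
    return Corpus(documents=docs, provenance="medline-xml")


_JSONL_KEYS = ("doc_id", "title", "abstract", "compound_query")


def read_jsonl(stream: str | IO[str]) -> Corpus:
    """Read a corpus from JSONL (one object per line, keys doc_id / title /
    abstract / compound_query); documents with empty abstracts are dropped."""
    lines = stream.splitlines() if isinstance(stream, str) else stream
    docs = []
    dropped = 0
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise ValueError(f"JSONL line {lineno}: {exc}") from exc
        if not str(obj.get("doc_id", "")):
            raise ValueError(f"JSONL line {lineno}: missing doc_id")
        if not str(obj.get("abstract", "")).strip():
            dropped += 1
            continue
        docs.append(Document(
            doc_id=str(obj["doc_id"]),
            title=str(obj.get("title", "")),
            abstract=str(obj["abstract"]),
            compound_query=str(obj.get("compound_query", "")),
        ))
    if dropped:
        logger.info("read_jsonl: dropped %d document(s) with empty abstracts", dropped)
    return Corpus(documents=docs, provenance="jsonl")


def write_jsonl(corpus: Corpus, stream: IO[str]) -> None:
    """Write one UTF-8 JSON object per line with keys in fixed order."""
    for doc in corpus.documents:
        obj = {k: getattr(doc, k) for k in _JSONL_KEYS}
        stream.write(json.dumps(obj, ensure_ascii=False) + "\n")


def _normalize_text(text: str) -> str:
    return re.sub(r"\s+", " ", text.lower()).strip()


def dedupe(corpus: Corpus) -> Corpus:
    """Remove duplicate documents; first occurrence wins, order preserved.

    A document is a duplicate if its ``doc_id`` was already seen or the
    SHA-1 of its normalized abstract (lowercased, whitespace-collapsed)
    was already seen.
    """
    seen_ids: set[str] = set()
    seen_hashes: set[str] = set()
    kept = []
    for doc in corpus.documents:
        digest = hashlib.sha1(_normalize_text(doc.abstract).encode()).hexdigest()
        if doc.doc_id in seen_ids or digest in seen_hashes:
            continue
        seen_ids.add(doc.doc_id)
        seen_hashes.add(digest)
        kept.append(doc)
    return Corpus(documents=kept, provenance=corpus.provenance)


def cap_per_query(corpus: Corpus, limit: int = DEFAULT_ABSTRACT_CAP) -> Corpus:
    """Keep at most the first ``limit`` documents per ``compound_query``
    value, in ingestion order (the screening protocol's per-compound cap)."""
    if limit < 1:
        raise ValueError(f"limit must be >= 1, got {limit}")
    counts: dict[str, int] = {}
    kept = []
    for doc in corpus.documents:
        counts[doc.compound_query] = counts.get(doc.compound_query, 0) + 1
        if counts[doc.compound_query] <= limit:
            kept.append(doc)
    return Corpus(documents=kept, provenance=corpus.provenance)


def fetch_pubmed(compounds: Iterable[str], email: str, limit: int = DEFAULT_ABSTRACT_CAP) -> Corpus:
    """Fetch abstracts from PubMed E-utilities (network required).

    Runs :func:`build_pubmed_query` per compound, esearch + efetch via
    Biopython's Entrez module, and applies the per-compound cap.  Not
    exercised by the offline test suite.
    """
    from Bio import Entrez  # optional dependency, network path only

    Entrez.email = email
    all_docs: list[Document] = []
    for compound in compounds:
        query = build_pubmed_query(compound)
        with Entrez.esearch(db="pubmed", term=query, retmax=limit) as handle:
            record = Entrez.read(handle)
        ids = record.get("IdList", [])
        logger.info("fetch: %s -> %d id(s)", compound, len(ids))
        if not ids:
            continue
        with Entrez.efetch(db="pubmed", id=",".join(ids), rettype="xml") as handle:
            sub = read_medline_xml(handle.read(), compound_query=compound)
        all_docs.extend(sub.documents)
    return cap_per_query(dedupe(Corpus(documents=all_docs, provenance="pubmed")), limit)
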