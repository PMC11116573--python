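"""End-to-end orchestration with reproducible run manifests.

A run is described by one TOML config file::

    [input]
    corpus = "fixtures/corpus.jsonl"     # JSONL abstracts
    conllu = "fixtures/gold.conllu"      # pre-parsed dependency trees
    lexicon = "fixtures/lexicon.tsv"     # entity gazetteer
    # verbs = "my_verbs.txt"             # optional causal-verb override
    # synonyms = "synonyms.tsv"          # optional key unification table

    [params]
    cap = 100                            # per-compound abstract cap
    compare_threshold = 0.8

    [output]
    out_dir = "runs/demo"

    [[compare]]
    reference = "fixtures/aop_synthetic.json"

Stages: ingest → parse (CoNLL-U) → ner → extract → graph build → exports
→ optional AOP comparison.  Every edge in the output graph is traceable to
a (doc_id, sent_id, sentence text) evidence record, and the manifest
written next to the outputs snapshots the config, input digests and
per-stage counts so a rerun can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .aop_benchmark import compare as aop_compare
from .aop_benchmark import load_aop_reference
from .causal_relex import (extract_relations, load_causal_verbs,
                           write_relations_tsv)
from .corpus_io import cap_per_query, dedupe, read_jsonl, write_jsonl
from .entity_recognition import (load_lexicon, match_entities,
                                 normalize_mention, write_mentions_tsv)
from .knowledge_graph import (build_graph, export_cypher, export_graphml,
                              export_neo4j_csv)
from .parse_layer import read_conllu

logger = logging.getLogger(__name__)

__all__ = ["PipelineError", "RunManifest", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure; message carries the stage name and offending record."""


@dataclass
class RunManifest:
    config: dict
    input_digests: dict[str, str]
    stage_counts: dict[str, int] = field(default_factory=dict)
    version: str = __version__
    seed: int | None = None

    def to_json(self) -> str:
        return json.dumps({
            "config": self.config,
            "input_digests": self.input_digests,
            "stage_counts": self.stage_counts,
            "version": self.version,
            "seed": self.seed,
        }, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _log(stage: str, **counts: int) -> None:
    logger.info(json.dumps({"stage": stage, **counts}))


def run_pipeline(config_path: str | Path, log_stream=None) -> RunManifest:
    """Execute a configured run end-to-end; returns the manifest.

    Startup validation checks that all referenced inputs exist before any
    stage runs; any stage failure aborts with the stage name and offending
    record id.
    """
    if log_stream is None:
        log_stream = sys.stderr
    config_path = Path(config_path)
    with config_path.open("rb") as fh:
        config = tomllib.load(fh)

    inputs = config.get("input", {})
    params = config.get("params", {})
    out_dir = Path(config.get("output", {}).get("out_dir", "toxkg_run"))

    paths: dict[str, Path] = {}
    for key in ("corpus", "conllu", "lexicon", "verbs", "synonyms"):
        if key in inputs:
            paths[key] = Path(inputs[key])
            if not paths[key].is_file():
                raise PipelineError(f"startup: input {key!r} not found: {paths[key]}")
    for key in ("corpus", "conllu", "lexicon"):
        if key not in paths:
            raise PipelineError(f"startup: config [input].{key} is required")
    ref_paths = [Path(c["reference"]) for c in config.get("compare", [])]
    for ref in ref_paths:
        if not ref.is_file():
            raise PipelineError(f"startup: compare reference not found: {ref}")

    manifest = RunManifest(
        config=config,
        input_digests={k: _sha256(p) for k, p in sorted(paths.items())},
        seed=params.get("seed"),
    )

    # --- ingest
    try:
        corpus = read_jsonl(paths["corpus"].read_text(encoding="utf-8"))
    except ValueError as exc:
        raise PipelineError(f"ingest: {exc}") from exc
    n_in = len(corpus)
    corpus = cap_per_query(dedupe(corpus), limit=int(params.get("cap", 100)))
    manifest.stage_counts["documents_in"] = n_in
    manifest.stage_counts["documents_kept"] = len(corpus)
    _log("ingest", documents_in=n_in, documents_kept=len(corpus))

    # --- parse
    try:
        sentences = read_conllu(paths["conllu"].read_text(encoding="utf-8"))
    except ValueError as exc:
        raise PipelineError(f"parse: {exc}") from exc
    kept_ids = {d.doc_id for d in corpus}
    sentences = [s for s in sentences if not s.doc_id or s.doc_id in kept_ids]
    manifest.stage_counts["sentences"] = len(sentences)
    _log("parse", sentences=len(sentences))

    # --- ner
    try:
        lexicon = load_lexicon(paths["lexicon"].read_text(encoding="utf-8"))
    except ValueError as exc:
        raise PipelineError(f"ner: {exc}") from exc
    synonyms = None
    if "synonyms" in paths:
        synonyms = {}
        for line in paths["synonyms"].read_text(encoding="utf-8").splitlines():
            if line.strip() and not line.startswith("#"):
                src, _, dst = line.partition("\t")
                synonyms[src.strip()] = dst.strip()
    mentions_by_sent = {}
    n_mentions = 0
    for sent in sentences:
        ms = match_entities(sent, lexicon)
        if synonyms:
            import dataclasses
            ms = [dataclasses.replace(m, key=normalize_mention(m, synonyms))
                  for m in ms]
        mentions_by_sent[(sent.doc_id, sent.sent_id)] = (sent, ms)
        n_mentions += len(ms)
    manifest.stage_counts["mentions"] = n_mentions
    _log("ner", mentions=n_mentions)

    # --- extract
    verbs = load_causal_verbs(
        paths["verbs"].read_text(encoding="utf-8").splitlines()
        if "verbs" in paths else None)
    relations = []
    for sent, ms in mentions_by_sent.values():
        relations.extend(extract_relations(sent, ms, verbs))
    manifest.stage_counts["relations"] = len(relations)
    _log("extract", relations=len(relations))

    # --- graph build + exports
    graph = build_graph(relations)
    manifest.stage_counts["nodes"] = len(graph.nodes)
    manifest.stage_counts["edges"] = len(graph.edges)
    _log("graph", nodes=len(graph.nodes), edges=len(graph.edges))

    out_dir.mkdir(parents=True, exist_ok=True)
    with (out_dir / "corpus.jsonl").open("w", encoding="utf-8") as fh:
        write_jsonl(corpus, fh)
    with (out_dir / "mentions.tsv").open("w", encoding="utf-8") as fh:
        write_mentions_tsv(
            (m for _, ms in mentions_by_sent.values() for m in ms), fh)
    with (out_dir / "relations.tsv").open("w", encoding="utf-8") as fh:
        write_relations_tsv(relations, fh)
    export_neo4j_csv(graph, out_dir)
    (out_dir / "graph.graphml").write_text(export_graphml(graph), encoding="utf-8")
    (out_dir / "graph.cypher").write_text(export_cypher(graph), encoding="utf-8")

    # --- optional AOP comparison
    reports = []
    for ref_path in ref_paths:
        try:
            reference = load_aop_reference(ref_path.read_text(encoding="utf-8"))
        except ValueError as exc:
            raise PipelineError(f"compare: {ref_path}: {exc}") from exc
        report = aop_compare(reference, graph,
                             threshold=float(params.get("compare_threshold", 0.8)))
        reports.append(report.to_dict())
        _log("compare", aop=int(report.aop_id) if report.aop_id.isdigit() else -1,
             matched_events=len(report.matched_events))
    if reports:
        (out_dir / "comparison.json").write_text(
            json.dumps(reports, indent=2, sort_keys=True), encoding="utf-8")

    (out_dir / "manifest.json").write_text(manifest.to_json() + "\n", encoding="utf-8")
    return manifest
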