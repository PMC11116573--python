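# Methods

## Model

`toxkg` extracts oriented causal relations between chemical compounds and
biological phenotypes from sentence-level dependency trees. The rule is
deliberately simple and auditable:

1. **Entity recognition.** A gazetteer maps lowercased token sequences to
   `COMPOUND` or `PHENOTYPE`. Matching is greedy longest-match,
   left-to-right, over token forms with a lemma fallback (a phrase matches
   if either all forms or all lemmas match); overlapping candidates are
   resolved longest-span-first, ties leftmost, and matched tokens are
   consumed. Longest-match is a deliberate corrective: nested chemical
   names ("valproic acid sodium salt" ⊃ "valproic acid") must resolve to
   the outer name, a known weak spot of span-based statistical
   recognizers. A mention's node key is the lowercased space-joined lemma
   sequence of its span; an optional synonym table can merge keys
   ("hepatic steatosis" → "liver steatosis"), and without one distinct
   phrasings deliberately remain distinct nodes.

2. **Relation detection.** Two mentions in one sentence are causally
   related iff a token with `upos = VERB` whose lemma is in the causal-verb
   set is a *strict* common ancestor of both mention head tokens (the head
   of a multiword span is its leftmost token whose own head lies outside
   the span). Lemma matching makes the rule conjugation-invariant. Only
   compound–phenotype and phenotype–phenotype pairs are eligible;
   compound–compound pairs are skipped by default.

3. **Orientation.** The detection rule is symmetric, so direction is a
   separate heuristic: for each mention, the verb's child on the mention's
   ancestor path is classified by UD relation — cause-roles
   {`nsubj`, `csubj`, `obl:agent`}, effect-roles {`obj`, `iobj`,
   `nsubj:pass`, `csubj:pass`, `obl`, `ccomp`, `xcomp`, `advcl`, `nmod`};
   subtype labels are tried verbatim first, then by their base relation
   before ":". If exactly one mention carries a cause-role the orientation
   is `SYNTACTIC`; otherwise the earlier mention in the sentence is the
   cause and the relation is flagged `LINEAR_FALLBACK`, so downstream
   consumers can ignore direction where the heuristic is weak.

4. **Graph merging.** One node per normalized key (labels decided by
   majority over observed mentions; a tie between COMPOUND and PHENOTYPE
   resolves to COMPOUND with both counts retained, preserving genuine
   label ambiguity such as "oxygen" used for reactive oxygen species),
   one directed edge per ordered key pair, verb sets merged, evidence
   deduplicated on (doc, sentence, verb, source, target). The invariant
   Σ evidence_count = number of unique input relations is asserted by
   tests and the acceptance script.

5. **Pathway benchmark.** AOP references (events typed MIE/KE/AO, plus
   KER arcs) are matched to graph nodes by token-set
   intersection-over-union after normalizing AOPWiki-style titles
   (stripping the leading "Increased,"-type qualifier, lowercasing,
   dropping punctuation). A KER counts as recovered when both endpoints
   matched and an edge exists between the matched nodes —
   direction-agnostic by default, because the extractor's orientation is
   itself heuristic. A *shortcut* is an extracted edge between matched
   events connected in the reference only by a directed path of length
   ≥ 2. References with a single event load but are flagged and excluded
   from fraction aggregation.

## Assumptions

- Relations are sentence-local: no cross-sentence linking, no coreference.
- "Causal verb" requires `upos = VERB`: nominal uses of listed lemmas
  ("an increase in ALT") do not trigger.
- Strict ancestry (the verb equals neither entity head) means participial
  constructions where the effect heads the clause ("steatosis caused by
  X") are missed; this trades a documented recall loss for a literal,
  predictable rule.
- Coordinated subjects each receive their own relation. This is
  recall-oriented and produces a characteristic false positive when a
  protective compound is co-mentioned with a causal one; the synthetic
  corpus plants this pattern on purpose and the evaluator reports it
  separately.

## Parameters

| parameter | default | meaning |
|---|---|---|
| causal-verb list | shipped 22-lemma set | lemmas eligible as causal ancestors; overridable text file, lowercased + deduplicated on load |
| per-compound abstract cap | 100 | first-N-per-query screening cap at ingestion, in input-stream order |
| event-match threshold | 0.8 | minimum token-set IoU for an AOP event ↔ node match; a CLI flag because any automated matcher reconstructs what is otherwise manual curation |
| relation policy | compound–phenotype, phenotype–phenotype | eligible label pairs |
| `strict_direction` | off | require edge direction to agree with KER direction in the benchmark |

## Synthetic corpus

The generator emits abstracts of templated sentences with hand-built UD
trees, so tests need no parser and the gold standard is exact. Templates:
ACTIVE ("X induces Y in rats", weight 0.35), PASSIVE ("Y is induced by X",
0.25), COORDINATED ("X₁ and X₂ induce Y", 0.15 — the second conjunct is
the planted true cause, the first the planted expected false positive),
DISTRACTOR ("X was measured in patients with Y", 0.25 — no causal verb).
Defaults: 200 abstracts of 3–6 sentences, 8 compounds × 8 phenotype
phrases (disjoint), seed 7. The random stream is consumed in a fixed
order per sentence (template, then vocabulary, then verb) so adding
templates cannot silently shift existing draws.

What passing means: closure (precision = recall = 1.0 without the
COORDINATED template; recall = 1.0 with it, and precision exactly
gold/(gold + planted FPs)) verifies the machinery end-to-end, but the
corpus has no negation, hedging, anaphora, parser errors,
out-of-vocabulary entities or nominalized causality — scores on real
abstracts will be lower and are not claimed here.

## Numerical and format choices

- CoNLL-U: multiword-token and empty-node lines are skipped; unknown UPOS
  tags map to `X`; a missing lemma falls back to the lowercased form; the
  canonical writer emits `_` for unused columns and fixed-order comments,
  making `write(read(x))` a fixed point.
- All exports (Neo4j bulk-import CSV, GraphML, Cypher) sort rows by key
  and are byte-deterministic functions of the graph.
- Dedup at ingestion: first occurrence wins, by doc id or by SHA-1 of the
  lowercased whitespace-collapsed abstract.
- Tie-breaks are lexicographic everywhere a choice is otherwise arbitrary
  (event matching, display names, export ordering).
- When several verbs of the same lemma dominate a pair, one relation per
  distinct lemma is emitted and the verb nearest the entity heads carries
  provenance and orientation.
- Empty-prediction precision is reported as 1.0, flagged in the result.

## Problem sizes

The oracle-equivalence checks use 1,000 random recursive trees of 3–15
tokens with random spans and lemmas; conservation checks use 100 random
relation lists; closure runs on the default 200-abstract corpus. These
sizes give stable, exact (not statistical) assertions — every check is an
identity, not an approximation — while keeping the full suite in the
low seconds.

## Known limitations

- The shipped AOP reference files are synthetic illustrations of the JSON
  schema (marked `_synthetic`), not transcriptions of live AOPWiki
  entries; users benchmark against their own transcriptions.
- The lexicon recognizer cannot find entities it has not been given;
  statistical recognizers plug in via a character-span contract
  (partial-token spans are rejected with a warning).
- Orientation of symmetric constructions depends on the role table; all
  fallback decisions are flagged, never silent.
- Live PubMed fetching (`toxkg fetch`) requires the network and the
  optional Biopython dependency and is not exercised by the offline test
  suite.
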