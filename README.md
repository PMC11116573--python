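# toxkg

Causal knowledge graphs of compounds and phenotypes from toxicology
abstracts.

Toxicologists screening chemicals for adverse outcomes such as liver
**cholestasis** (bile accumulation) or **steatosis** (lipid-droplet
accumulation) face a literature too large to curate by hand. `toxkg`
implements a rule-based text-mining pipeline that turns dependency-parsed
PubMed abstracts into a queryable, provenance-tracked graph of causal
claims, so that every edge can be traced back to the exact sentence and
article it came from — and scores the resulting graph against adverse
outcome pathway (AOP) references.

## The extraction rule

Entities of two kinds — `COMPOUND` (a chemical or substance) and
`PHENOTYPE` (a biological event at any level of organization) — are
matched in each sentence by a deterministic gazetteer (longest match wins,
with a lemma fallback). Two entities *e₁, e₂* in a sentence are considered
causally related iff some token *v* with `upos = VERB` and
`lemma(v) ∈ V` is a strict common ancestor of both entity head tokens in
the sentence's Universal Dependencies tree:

```
v ∈ anc(head(e₁)) ∩ anc(head(e₂)),   lemma(v) ∈ V,   v ∉ {head(e₁), head(e₂)}
```

where `V` is a configurable list of causal verb lemmas (the shipped
default has 22 unique lemmas: *increase, produce, cause, induce, …,
inhibit, elevate, diminish*). Matching by lemma makes the rule insensitive
to conjugation. Direction is assigned from the UD role of the verb's child
on each entity's path — subject-like (`nsubj`, `csubj`, `obl:agent`) ⇒
cause; object/oblique-like ⇒ effect — with a flagged linear-order fallback
when roles do not disambiguate.

Relations merge into a directed graph (one edge per ordered entity pair,
with verb set and per-sentence evidence list); first-level-neighbor
queries answer "which compounds are linked to this adverse outcome?"; and
the AOP benchmark reports which pathway events and key event relationships
(KERs) the graph recovered, including *shortcut* edges that connect
non-adjacent events (e.g. a molecular initiating event straight to the
adverse outcome).

No parser is bundled: the pipeline consumes CoNLL-U from any UD parser, or
the built-in synthetic corpus generator, which emits abstracts with exact
hand-constructed gold trees, entities and relations for hermetic testing.

## Worked example

```sh
toxkg simulate --seed 7 --n-docs 200 --out-dir fixtures/
toxkg extract --conllu fixtures/gold.conllu --lexicon fixtures/lexicon.tsv \
      --out relations.tsv
toxkg evaluate --predicted relations.tsv --gold fixtures/gold_relations.tsv \
      --expected-fp fixtures/expected_fp.tsv --forgive-known
```

prints

```
precision	1.0000
recall	1.0000
f1	1.0000
true_positives	659
false_positives	0
false_negatives	0
known_false_positives	141
```

Recall and precision are perfect on the planted relations; the 141
`known_false_positives` are the deliberately planted coordinated-subject
sentences ("A and B induce C", where A is e.g. a protective compound
mentioned alongside the causal one) — a real, documented failure mode of
the ancestor rule that the generator reproduces and the evaluator accounts
for separately. Querying the graph then mirrors the compound screen:

```sh
toxkg graph query --relations relations.tsv --key steatosis --label COMPOUND
```

lists every compound node one hop from "steatosis", each backed by listed
evidence sentences. `toxkg run --config run.toml` executes the whole chain
(ingest → parse → ner → extract → graph → compare) and writes a manifest
with input digests and per-stage counts for byte-reproducible runs;
`toxkg graph build` exports Neo4j bulk-import CSV, GraphML and Cypher.

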