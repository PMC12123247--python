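# Methods

## The matching cascade

A query term is normalized (Unicode NFC, casefold, trim, collapse internal
whitespace runs, strip symmetric surrounding quotes; punctuation preserved)
and passed through three tiers:

1. **Exact.** Every concept whose normalized name equals the normalized query
   becomes a candidate with similarity exactly 1.0. This is a contract, not a
   computed score: surface variation in case, spacing, or quoting never costs
   an exact match anything.
2. **Linguistic.** If a synonym table maps the normalized query to concept
   ids, those concepts are *guaranteed* candidates. Their similarity is the
   embedding cosine between query and concept name, floor-bounded at the
   configurable `linguistic_floor` (default 0.0) so that a curated
   association can never be pushed out by unfavorable embedding geometry
   alone. The synonym table is a deliberately generic two-column realization
   (normalized text → concept_id): any richer resource — UMLS synonym sets,
   local code lists — reduces to it, and nothing in the cascade depends on
   how the associations were produced.
3. **Embedding.** Remaining slots up to `k` (default 5) are filled by the
   top cosine-similarity concepts over the precomputed index.

Candidates are sorted by similarity descending with a deterministic total
tie-break: earlier tier first, then standard concepts before non-standard
(OMOP analytics prefer standard concepts), then ascending concept_id. The
tier component of the key matters only when a non-exact candidate also
reaches cosine 1.0 (identical normalized text can do this); it guarantees
the exact-tier candidate still occupies rank 1. Within the embedding tier the
ordering is identical to an exhaustive cosine scan with the
standard-first/ascending-id tie-break, and the test suite asserts this
equivalence against a brute-force oracle.

The similarity `cutoff` (default 0.85, the loosest cutoff of the canonical
sweep) only *flags* candidates as sub-threshold; it never changes membership
or order. Flagged-not-dropped matters twice: reviewers choosing among ranked
alternatives still see near-misses, and an entire threshold sweep can be
evaluated from a single matching pass.

## The reference embedding provider

Production deployments of embedding-based mappers use large-language-model
embedding services. Those are non-deterministic across model revisions and
unusable offline, so the package's default provider is a deterministic
hashed character-n-gram embedder:

* normalize the text (same function as the exact tier);
* pad with boundary markers and extract character 3-grams;
* hash each 3-gram with a keyed BLAKE2b hash (key = the seed) to a bucket in
  `[0, dimension)` and a sign in {−1, +1};
* accumulate and L2-normalize.

Defaults: dimension 512, seed 42, recorded in the index header. Identical
(text, dimension, seed) always produce bit-identical vectors on any machine.
This is the feature-hashing construction used by fastText-style subword
models; it captures *surface* similarity (shared character n-grams), not
semantics. Consequences worth being explicit about:

* Typos and word-order changes degrade similarity smoothly — good for
  exercising cutoff behavior.
* True paraphrases ("marital status" vs "relationship status") are *not*
  close in this geometry the way they are for an LLM embedding. Published
  similarity values from LLM-backed deployments (e.g. 93.89% for a
  near-variant pair) are provider-specific and are not reproduced by the
  reference provider, by design.
* Empty text embeds to the zero vector (with a warning); cosine with a zero
  vector is defined as 0.

A remote provider can implement the same contract (`provider_id`,
`dimension`, `embed`, `config_header`). Index files carry a self-describing
header (provider id, dimension, seed, normalization spec) and loading an
index under a mismatched session configuration is refused outright — silently
comparing vectors from different providers is the worst failure mode of a
precomputed-index design.

## Vocabulary handling

The Athena CONCEPT table is tab-delimited with ten named columns; dates are
`YYYYMMDD`. Empty `standard_concept` maps to "non-standard", `S` to
"standard", `C` to "classification". Rows with unparseable concept_ids,
empty names, or reversed validity dates are rejected *with a per-row report*
(row number and reason); duplicate concept_ids abort the load. A concept is
currently valid iff `invalid_reason` is empty. Whether non-standard or
invalidated concepts belong in the matching index is left to the caller via
filter flags (`standard_only`, `valid_only`) rather than hard-coded, since
deployments differ on this.

## Evaluation

Per query the prediction is the rank-1 candidate. At cutoff *t*: similarity
≥ *t* and concept equals gold → TP; ≥ *t* and differs (or gold is NONE) →
FP; < *t* (or no candidate) with gold NONE → TN; otherwise FN. Precision,
recall and F1 = 2PR/(P+R) follow, with degenerate denominators defined as 0.
This rank-1-above-cutoff operationalization makes recall monotone
non-increasing in the cutoff while precision saturates — the familiar shape
of published threshold-sweep tables. Note that tp+fn is *not* invariant
across cutoffs under these rules: an asserted-but-wrong prediction counts FP
at a loose cutoff and FN once the cutoff excludes it; the conserved quantity
is the total query count.

The AUC is the Mann–Whitney rank statistic over per-query top-1 scores:
label 1 iff the rank-1 concept equals gold, score = rank-1 similarity, AUC =
P(random correct query outscores a random incorrect one) with ties counting
½, computed via average ranks. Top-1 scores (not all candidate scores) are
used because the quantity of interest is per mapped term. With a single
class the AUC is undefined and reported as such (`None`; the CLI prints
"undefined"). A brute-force pairwise-counting oracle and scikit-learn's
`roc_auc_score` both cross-check the implementation in the tests.

The gold standard joins on a query identifier: the record's `field_id` when
present, else the query text. The fixture generator emits synthetic query
ids (`q0000`, ...) as field ids so joins are exact even with duplicate
query texts.

## Synthetic fixtures

`fixtures.FixtureSpec` defines the study conditions for one synthetic
dataset. Defaults — 500 concepts over two vocabularies (LOINC, SNOMED), 200
queries, variant mix 25% identical / 20% case change / 15% whitespace change
/ 10% synonym swap / 10% token shuffle / 20% single-character typo, no
unmappable queries unless requested — are a desk-scale version of a
CDE-mapping evaluation: enough concepts that the embedding tier has real
distractors, enough queries for stable sweep rows, and a variant mix spanning
"trivially recoverable" to "genuinely lossy" surface noise. Concept names
are assembled from a built-in list of ~200 clinical tokens (symptoms,
findings, demographics, survey phrasing) and are unique after casefolding,
so the exact tier is unambiguous. Typos are a single substitution or
deletion at a seeded position. Everything is deterministic in the spec seed;
regeneration is byte-identical.

What passing on these fixtures shows: the plumbing is correct — parsing,
cascade ordering, tie-breaks, flag semantics, metric arithmetic, export
completeness. What it does not show: mapping quality on real clinical terms
under a real LLM embedding geometry. The fixtures deliberately do not
emulate that geometry, and no synthetic AUC or sweep row should be read as a
claim about real-data performance.

## Numerical and design choices

* Similarity is reported to 4 decimals in outputs; percent formatting is a
  display concern of the writer.
* Vectors are float64; unit norm within 1e-9; cosine clipped to [−1, 1].
* Output CSV: UTF-8, comma-delimited, all fields quoted, header always
  written; a query with zero candidates still gets a row (empty concept
  columns) so exports are complete. Every metadata cell is written from, and
  verified against, the loaded vocabulary collection; divergence raises an
  integrity error instead of producing a discordant export.
* REDCap parsing excludes `descriptive` and `calc` fields and the record-id
  field (the dictionary's first field) from mapping — structural content,
  not clinical content — but reports them, and the parse is loss-accounted:
  mappable records + excluded entries + choice-parse failures = fields +
  choices. The exclusion set is configurable because REDCap usage varies.
* CLI runs write a manifest (effective config + SHA-256 of inputs) beside
  each output; exit codes distinguish total (1) from partial (2) failure.

## Known limitations

* The reference provider's geometry is lexical; synonym-level semantics must
  come from the synonym table or a plugged-in LLM provider.
* Similarity search is a dense matrix product — fine to ~10⁵ concepts,
  not engineered for the full multi-million-concept vocabulary (no
  approximate-nearest-neighbor structure).
* Only the CONCEPT table is consumed; concept relationships and ancestry
  (CONCEPT_RELATIONSHIP, CONCEPT_ANCESTOR) are out of scope, as are live
  REDCap API integration and XLSX output.
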