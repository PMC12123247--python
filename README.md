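# omopmap

Mapping heterogeneous clinical terms — data-dictionary labels, survey answer
choices, free-text variable names — onto OMOP/OHDSI standardized vocabulary
concepts is the gating step for pooling clinical-study data into the OMOP
Common Data Model. Doing it by hand takes informatics expertise most small
research teams do not have. `omopmap` automates the step with a three-tier
semantic matching cascade over an OHDSI Athena-format vocabulary table:

1. **Exact match** — direct string correspondence between the normalized
   query and a concept name yields a candidate with similarity exactly 1.0.
2. **Linguistic association** — a curated synonym table guarantees inclusion
   of concepts known to denote the same idea under different phrasing.
3. **Embedding similarity** — remaining candidate slots are filled by cosine
   similarity between the query embedding and precomputed embeddings of every
   concept name, so "chest pain during physical activity"-style paraphrases
   still surface "exercise-induced angina"-style concepts.

Candidates are ranked by similarity (ties: earlier tier, standard concepts
first, ascending `concept_id`), flagged when they fall below a configurable
cutoff, and exported to a CSV carrying the complete vocabulary metadata for
each match. An evaluation harness scores mapping runs against an expert gold
standard with precision/recall/F1 across a sweep of similarity cutoffs
(F1 = 2PR/(P+R)) plus a rank-based (Mann–Whitney) AUC over top-1 scores.

Embeddings sit behind a provider contract. The built-in reference provider is
a deterministic seeded hashed character-3-gram embedder (fastText-style
feature hashing, L2-normalized), so everything runs offline and reproducibly;
an external LLM embedding service can be plugged in behind the same contract.
A fixture generator produces synthetic Athena-dialect vocabularies, query sets
with gold labels, synonym tables, and REDCap data dictionaries, so the whole
pipeline is testable without downloading licensed vocabularies.

## Worked example

Build an index over a small demographic vocabulary and map one answer term:

```sh
omopmap index --vocabulary CONCEPT.tsv --out index.npz
omopmap map "Not Hispanic or Latino" --index index.npz --vocabulary CONCEPT.tsv --k 3
```

```
query: Not Hispanic or Latino  (normalized: not hispanic or latino)
rank  similarity  tier        concept_id  code          vocabulary  name
   1  1.0000      exact       2001        LA19555-4     LOINC       Not Hispanic or Latino
   2  0.8543      embedding   2003        LA6214-6      LOINC       Hispanic or Latino
   3  0.8182      embedding   2002        LA10597-5     LOINC       Non-Hispanic or Latino *below cutoff*
```

The query is character-identical to the LOINC answer concept LA19555-4, so
the exact tier places it at rank 1 with 100% similarity; the embedding tier
fills the remaining slots with near-variants, and anything under the 0.85
cutoff is flagged rather than hidden.

A full synthetic run — 500 concepts, 200 queries with realistic surface
variation (case/whitespace changes, synonym swaps, token shuffles, typos) and
5% deliberately unmappable queries:

```sh
omopmap fixtures --out-dir data --n-concepts 500 --n-queries 200 --seed 1 --none-fraction 0.05
omopmap index    --vocabulary data/CONCEPT.tsv --out data/index.npz
omopmap batch    --input data/queries.csv --kind terms --index data/index.npz \
                 --vocabulary data/CONCEPT.tsv --out data/mapped.csv
omopmap evaluate --results data/mapped.csv --gold data/gold.csv
```

```
mapped=200 sub_threshold=32 failed=0 -> data/mapped.csv
cutoff  precision  recall  f1      tp   fp   fn   tn
0.85    1.0000     0.8936  0.9438  168  0    20   12
0.88    1.0000     0.8245  0.9038  155  0    33   12
0.9     1.0000     0.8032  0.8909  151  0    37   12
0.92    1.0000     0.7394  0.8502  139  0    49   12
0.95    1.0000     0.6862  0.8139  129  0    59   12
0.97    1.0000     0.6809  0.8101  128  0    60   12
0.99    1.0000     0.6809  0.8101  128  0    60   12
AUC: 0.9991
```

Reading the table: at cutoff 0.85 every asserted mapping is correct
(precision 1), 89% of mappable queries are recovered, and the 12 unmappable
queries are correctly left unasserted (TN). Tightening the cutoff trades
recall for stringency while precision stays saturated — the canonical shape
of a threshold sweep — and the AUC says top-1 similarity almost perfectly
separates correct from incorrect mappings on this synthetic set.

REDCap data dictionaries map the same way (`--kind redcap`): each field label
and each parsed answer-choice label ("1, Married | 2, Single" → "Married",
"Single") becomes a query; descriptive/calculated fields and the record-id
field are excluded from mapping but reported, never silently dropped.

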