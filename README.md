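# ontomap

Two-step harmonization of clinical records to target biomedical ontologies
(MONDO, HPO). Candidate (input, concept) mappings are generated with high
recall by either or both of two routes, then filtered for precision by a
pluggable semantic adjudicator:

1. **Embedding retrieval (RAG).** Every ontology label and synonym is
   embedded independently at the term level, `v = f(t)`, and stored with a
   `(text, url)` payload. An input's free text is embedded with the same
   model into a query `q`, and its top-k neighbours under cosine similarity
   `sim(q, v) = q·v / (‖q‖‖v‖)` become candidate concepts (k is a
   hyperparameter, default 3).
2. **SNOMED CT pivot.** Normalized ICD-10 codes (`Q87.8 → Q878`) are joined
   to MONDO/HPO concepts through shared SNOMED identifiers: the official
   SNOMED→ICD-10 extended map on one side, `SCTID:`/`SNOMEDCT_US:`
   cross-references harvested from the ontologies on the other. Codes with no
   result are classified by reason — (i) absent from the extended map, or
   (ii) mapped only to SNOMED ids without ontology cross-references.

Each candidate pair is then adjudicated under a fixed prompt that accepts the
candidate only if it denotes the same condition as the input or a broader
one (a directional subsumption test); responses must start with Y or N plus a
short justification. Agreement between two adjudicators (e.g. a model and a
human expert) is reported as a 2×2 contingency with percent agreement and
Cohen's kappa.

The package is aimed at data engineers and researchers harmonizing EHR-style
datasets: everything runs offline with a deterministic bundled embedder and a
mock adjudicator; adapters for remote embedding and chat endpoints satisfy
the same backend contracts for production use.

## Worked example

Generate a self-consistent toy world (ontology, extended map, records, and
planted ground truth) and run the full pipeline:

```sh
$ ontomap fixtures --seed 7 --out fx
wrote fixtures to fx
$ ontomap ingest --ontology fx/ontology.json
concepts=13 synonyms=26 xrefs=10
$ cat > config.yaml <<'YAML'
ontology_paths: [fx/ontology.json]
map_path: fx/map.tsv
records_path: fx/records.csv
generator: both
k: 3
out_dir: out
seed: 7
YAML
$ ontomap run --config config.yaml
INFO ontomap.pipeline stage=ingest concepts=13 records=12
INFO ontomap.pipeline stage=map-rag in=12 out=36
INFO ontomap.pipeline stage=map-pivot in=8 out=8 matched=4 no_snomed=2 no_xref=2
INFO ontomap.pipeline stage=adjudicate in=44 accepted=7
{
 "by_method": {
  "rag": {"n_accepted": 7, "n_pairs": 36, "n_rejected_with_error": 0, "ratio": 0.194},
  "snomed_pivot": {"n_accepted": 0, "n_pairs": 8, "n_rejected_with_error": 0, "ratio": 0.0}
 },
 "n_pairs": 44,
 "overall": {"n_accepted": 7, "n_pairs": 44, "n_rejected_with_error": 0, "ratio": 0.159}
}
```

Reading the output: 12 records at k=3 produced 36 retrieval candidates; of
the 8 distinct ICD-10 codes, 4 joined through SNOMED into 8 pivot pairs,
2 codes were absent from the extended map and 2 reached only SNOMED ids with
no ontology cross-reference. The mock adjudicator accepted exactly the 7
retrieval pairs whose record text equals a concept label (the fixture plants
such records on purpose); the pivot pairs stay rejected because a bare code
string never equals a concept label — supply an accept-table
(`accept_table_path`) or a remote adjudicator for semantic decisions.

`out/` then contains `pairs.jsonl` (one candidate per line with method,
score and matched term), `adjudications.jsonl` (decision, justification, raw
response), `coverage.json` (the per-code reason map shown above),
`fanout.json` (distinct targets per code, quantiles, share ≥ 10) and
`manifest.json` (config hash, seed, content digest of every artifact — with
offline backends, reruns are byte-identical).

The same stages are available individually (`ontomap index`, `map-rag`,
`map-pivot`, `adjudicate`, `evaluate`) and as library functions
(`ontomap.parse_obograph`, `build_index`, `search_topk`,
`generate_pivot_candidates`, `adjudicate`, `agreement_report`, …).

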