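# Methods

## The harmonization problem

Clinical records — free-text outcome descriptions, often accompanied by
ICD-10 codes — must be aligned to target biomedical ontologies (MONDO for
diseases, HPO for phenotypic abnormalities) before they can be pooled across
institutions. `ontomap` implements this as a two-step procedure that
separates recall from precision:

1. **Candidate generation** proposes (input, concept) pairs cheaply and with
   high recall, by either of two complementary routes (or their union):
   * *embedding retrieval (RAG)*: every ontology label and synonym is
     embedded independently at the term level; an input's text is embedded
     with the same model and its top-k nearest terms under cosine similarity
     become candidates;
   * *SNOMED pivot*: ICD-10 codes are joined to ontology concepts through
     SNOMED CT identifiers, using the SNOMED→ICD-10 extended map on one side
     and the SCTID / SNOMEDCT_US cross-references harvested from the
     ontologies on the other.
2. **Semantic adjudication** restores precision: each candidate pair is
   submitted to an adjudication backend under a fixed prompt that accepts the
   candidate only if it denotes the same condition or a broader one than the
   input (a directional subsumption test); a narrower candidate is rejected.

Only identifiers, labels, synonyms and cross-references of the ontologies
are used; definitions, descriptions and hierarchy edges are deliberately
ignored — the adjudicator, not graph reasoning, carries the semantics.

## Models and procedures

### Term-level embedding and retrieval

Each concept yields a family of vectors `{v_lbl, v_syn1, …, v_synk}`, one per
term, all carrying a `(text, url)` payload with the concept identifier.
Retrieval is an exhaustive cosine scan,
`sim(q, v) = q·v / (‖q‖‖v‖)`, returning the k best terms; k is a user
hyperparameter (default 3). Term hits sharing a concept are collapsed to one
pair per concept, keeping the best-scoring matched term, and the scan
continues until k *distinct concepts* are ranked — so a record yields exactly
`min(k, #concepts)` candidates and synonym crowding cannot starve the
candidate list. No score threshold is applied; every retrieved candidate goes
to adjudication. Approximate-nearest-neighbour indexes are intentionally
absent: at the tens-of-thousands-of-terms scale this package targets, the
exact scan is fast and removes a whole class of recall bugs.

The bundled offline embedder hashes padded character 3-grams (plus whole
words) into a signed `d`-dimensional bucket vector (default d=512) with a
keyed BLAKE2 hash and L2-normalizes it. It is bit-reproducible across
processes and machines — vectors depend only on the string, the dimension,
the n-gram order and the hash seed — which is what the determinism guarantees
below rest on. An adapter for remote embedding APIs (1536-dimensional
ada-002-style vectors) satisfies the same backend contract for production
use; nothing in the package or its tests requires it.

**Numerical note on ties.** Ranking sorts by non-increasing score with ties
broken lexicographically by `(payload_url, payload_text)`. Scores are
quantized to 12 decimals before ranking: BLAS matrix–vector products may
evaluate identical rows through different SIMD code paths, so two
bit-identical vectors can otherwise score apart by one ulp and escape the
tie-break, making run output depend on memory layout. At 1e-12 the
quantization is far below any semantically meaningful score difference.

### ICD-10 normalization and the pivot join

ICD-10 codes are uppercased and stripped of the decimal point and auxiliary
characters — whitespace, the dagger (†) and asterisk (*)
etiology/manifestation marks, and hyphen placeholders — so `Q87.8` becomes
`Q878`. The character set is configurable; normalization is idempotent. The
extended map is accepted in the official RF2 refset layout (rows with
`active != 1` or an empty `mapTarget` are dropped; no `mapGroup`/`mapPriority`
filtering is applied) or a minimal two-column TSV for small inputs.

The join is many-to-many with no uniqueness assumptions anywhere: a pair
(code, concept) is emitted iff some SNOMED id maps to the code and carries a
cross-reference to the concept, deduplicated on (code, concept) and stably
ordered. Codes that produce nothing are classified by reason: (i) the code
never occurs as a map target, or (ii) map rows exist but none of their SNOMED
ids is cross-referenced by the ontologies. The two tallies plus the matched
count always sum to the number of distinct input codes. Fan-out — the number
of distinct concepts per code — is summarized as a histogram with quantiles
and the share of codes at or above a threshold (default 10), because the
distribution is heavily right-skewed on real vocabularies and drives
adjudication workload.

### Adjudication protocol

The prompt is a versioned template: a fixed criteria block followed by
`Description 1` (the input text — always first) and `Description 2` (the
candidate's primary label). The default *strict* template accepts equivalent
or broader candidates; a *relaxed* template (same or related, more general or
more specific) ships alongside and is selected by configuration. Responses
must begin with `Y` or `N` (after stripping whitespace, quotes and markdown
decoration); any other leading character is an unparseable response, retried
once and then conservatively recorded as rejected-with-error — a mapping is
never accepted by default. Results preserve pair order and cardinality and
retain raw responses for audit.

The mock backend used in tests accepts exactly the pairs whose normalized
(case- and punctuation-insensitive) texts are equal, plus any pairs listed in
a user-supplied accept-table. This is deliberately *not* a model of LLM
judgment — it exists so end-to-end tests can plant known ground truth.

### Evaluation statistics

Two-adjudicator comparisons are reduced to a 2×2 contingency (both accept /
both reject / a-only / b-only); percent agreement is
`(both_accept + both_reject) / n × 100`, stored at full precision and
rendered at one decimal and at the nearest integer (published figures are
typically integer-rounded: a 1,285-of-1,401 contingency is 91.72%, printed as
92%). Cohen's kappa is computed as supplementary, chance-corrected output.
Acceptance summaries report the accepted share, with errored rejections
tallied separately. Review subsets are drawn uniformly without replacement
from an explicit seed and returned in input order, so review files are
byte-stable.

## Synthetic worlds and what they do (not) show

The fixture generator builds a self-consistent miniature world from one seed:
a toy ontology (default 8 MONDO + 5 HP concepts, 0–2 synonyms each, labels
drawn combinatorially from a bundled clinical-flavoured word list; synonyms
are deterministic perturbations — word swaps, abbreviations — that the
offline embedder ranks near their labels), a SNOMED pool (default 30 ids,
80% xref coverage), an extended map (80% coverage, plus planted inactive
rows), and records (default 12, of which 60% copy a concept label verbatim
and the rest are deliberately unrelated filler). Reason-(i) and reason-(ii)
codes are planted in known quantities (default 2 + 2). Ground truth —
every join-derivable (code, concept) pair and every planted exact-label
record — is constructed directly from the planted structure, never by
running the pipeline, so pipeline-vs-truth comparisons are genuinely
two-route.

Passing these tests shows the machinery is correct: parsers round-trip, the
join equals a brute-force oracle, retrieval equals a full scan, planted truth
is recovered with precision and recall 1.0, and artifacts are byte-identical
under a fixed seed. It says nothing about semantic quality on real clinical
text — fixture labels are structurally, not clinically, realistic; real
records are short, abbreviated and ambiguous, and real adjudication quality
depends on the language model behind the backend contract. Published
agreement levels on real data (roughly 78–92% against a human expert,
depending on the generator) cannot be reproduced offline and are not claimed
by any test here.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `k` | 3 | concepts retrieved per record; raising it trades adjudication workload for recall |
| embedding dimension | 512 offline / 1536 remote | hashed-bucket count; more buckets, fewer collisions |
| n-gram order | 3 | character-window size of the offline embedder |
| prompt template | `strict` | `strict` = equivalent-or-broader; `relaxed` = related-in-either-direction |
| auxiliary characters | `. † * -` + whitespace | stripped during ICD-10 normalization |
| seed | required | drives fixtures, sampling and the offline embedder's hash key |

## Problem sizes

Tests and the acceptance script run on miniature inputs chosen to exercise
every code path while completing in seconds: toy worlds of ~13 concepts and
~12 records; 100 random join instances (≤50 codes × ≤50 SNOMED ids × ≤40
concepts) against the nested-loop oracle; 100 random indexes (≤100 entries,
k ≤ 10, dimension 8, with planted duplicate vectors to exercise ties) against
the full-scan oracle.

## Known limitations

* The pivot join requires exact normalized-code equality; ICD-10 range
  targets in real extended maps (e.g. `M10-M14`) degrade to prefix strings
  rather than expanding.
* Concept-level collapsing keeps only the best-matched synonym per concept;
  per-synonym adjudication is not supported.
* The mock adjudicator validates plumbing, not judgment; agreement statistics
  computed against it characterize the pipeline, not any language model.
* Single-expert label files are supported as-is; no multi-annotator
  reconciliation beyond two-decision contingencies.
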