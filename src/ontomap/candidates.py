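"""Candidate mapping generation: embedding retrieval and the SNOMED pivot join.

Two complementary generators produce (input, target-concept) candidate pairs
awaiting adjudication:

* **RAG retrieval** — each record's free text is embedded with the same
  backend used for the index and its top-k nearest terms are retrieved by
  cosine similarity; hits sharing a concept are collapsed to one pair per
  concept, keeping the best-scoring matched term.

* **SNOMED pivot** — normalized ICD-10 codes are joined to MONDO/HPO concepts
  through shared SNOMED CT identifiers: one lookup maps SNOMED ids to ICD-10
  targets (the extended map), the other maps SNOMED ids to ontology concepts
  (harvested cross-references).  The join is many-to-many; unmatched codes are
  classified by failure reason — (i) the code never appears as a map target,
  or (ii) map rows exist but none of their SNOMED ids carries an ontology
  cross-reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .embeddings import EmbeddingBackend, VectorIndex, search_topk
from .ontology import CodeString, SnomedIcdMapEntry, XrefTable

logger = logging.getLogger(__name__)

__all__ = [
    "InputRecord",
    "CandidatePair",
    "PivotCoverageReport",
    "FanoutHistogram",
    "generate_rag_candidates",
    "generate_pivot_candidates",
    "fanout_histogram",
]

REASON_NO_SNOMED = "no_snomed_map"  # (i) ICD-10 not mentioned in SNOMED CT
REASON_NO_XREF = "no_ontology_xref"  # (ii) SNOMED id not cross-referenced


@dataclass(frozen=True)
class InputRecord:
    """One clinical input: an identifier, free text, optionally an ICD-10 code."""

    record_id: str
    text: str = ""
    icd10_code: Optional[CodeString] = None

    def __post_init__(self):
        if not self.text.strip() and self.icd10_code is None:
            raise ValueError(f"record {self.record_id!r} has neither text nor an ICD-10 code")


@dataclass(frozen=True)
class CandidatePair:
    """A proposed (source, target concept) mapping with provenance."""

    source_id: str
    source_text: str
    target_uri: str
    target_label: str
    method: str  # "rag" | "snomed_pivot"
    score: Optional[float] = None
    matched_text: Optional[str] = None

    def __post_init__(self):
        if self.method == "rag" and self.score is None:
            raise ValueError("rag pairs must carry a retrieval score")

    @property
    def key(self) -> tuple[str, str]:
        return (self.source_id, self.target_uri)


@dataclass
class PivotCoverageReport:
    """Per-code outcome tally of the pivot join.

    ``n_matched + n_unmatched_no_snomed + n_unmatched_no_xref == n_inputs``.
    """

    n_inputs: int = 0
    n_matched: int = 0
    n_unmatched_no_snomed: int = 0
    n_unmatched_no_xref: int = 0
    reason_by_code: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        total = self.n_matched + self.n_unmatched_no_snomed + self.n_unmatched_no_xref
        if total != self.n_inputs:
            raise AssertionError(
                f"coverage cells sum to {total}, expected n_inputs={self.n_inputs}"
            )

    def to_dict(self) -> dict:
        return {
            "n_inputs": self.n_inputs,
            "n_matched": self.n_matched,
            "n_unmatched_no_snomed": self.n_unmatched_no_snomed,
            "n_unmatched_no_xref": self.n_unmatched_no_xref,
            "reason_by_code": dict(sorted(self.reason_by_code.items())),
        }


@dataclass
class FanoutHistogram:
    """Distinct-target counts per input code, with summary quantiles."""

    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_pairs(self) -> int:
        return sum(self.counts.values())

    def quantiles(self, qs: Sequence[float] = (0.25, 0.5, 0.75, 0.9)) -> dict[float, float]:
        if not self.counts:
            return {q: float("nan") for q in qs}
        vals = np.asarray(sorted(self.counts.values()), dtype=np.float64)
        return {q: float(np.quantile(vals, q)) for q in qs}

    def share_at_or_above(self, threshold: int = 10) -> float:
        """Fraction of input codes mapping to >= threshold distinct targets."""
        if not self.counts:
            return 0.0
        return sum(1 for c in self.counts.values() if c >= threshold) / len(self.counts)

    def to_dict(self) -> dict:
        return {
            "counts": dict(sorted(self.counts.items())),
            "quantiles": {str(k): v for k, v in self.quantiles().items()},
            "share_fanout_ge_10": self.share_at_or_above(10),
        }


def generate_rag_candidates(
    records: Iterable[InputRecord],
    index: VectorIndex,
    backend: EmbeddingBackend,
    k: int,
) -> list[CandidatePair]:
    """Retrieve up to k candidate concepts per record by cosine similarity.

    The record text is embedded with the same backend used to build the index.
    Hits whose payloads share a concept identifier collapse to a single pair
    (keeping the highest-scoring matched term), so each record yields at most
    k concept-level pairs.  Records with empty text are skipped with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    pairs: list[CandidatePair] = []
    n_skipped = 0
    for record in records:
        if not record.text.strip():
            n_skipped += 1
            logger.warning("record %s has empty text; skipped by RAG generator", record.record_id)
            continue
        query = backend.embed(record.text)
        # retrieve extra hits so that concept-level dedup can still fill k
        hits = search_topk(index, query, k=max(k, len(index)))
        seen: dict[str, None] = {}
        for hit in hits:
            uri = hit.term.payload_url
            if uri in seen:
                continue
            seen[uri] = None
            pairs.append(
                CandidatePair(
                    source_id=record.record_id,
                    source_text=record.text,
                    target_uri=uri,
                    target_label=index.labels.get(uri, hit.term.payload_text),
                    method="rag",
                    score=hit.score,
                    matched_text=hit.term.payload_text,
                )
            )
            if len(seen) == k:
                break
    if n_skipped:
        logger.info("RAG generator skipped %d empty-text records", n_skipped)
    return pairs


def generate_pivot_candidates(
    codes: Iterable[CodeString],
    map_entries: Iterable[SnomedIcdMapEntry],
    xrefs: XrefTable,
) -> tuple[list[CandidatePair], PivotCoverageReport]:
    """Join ICD-10 codes to ontology concepts through SNOMED identifiers.

    A pair (code, concept) is emitted iff some SNOMED id maps to the code in
    the extended map and carries a cross-reference to the concept.  Output is
    deduplicated on (code, target_uri) and stably ordered.  Unmatched codes
    are classified: reason (i) no extended-map row targets the code; reason
    (ii) map rows exist but none of their SNOMED ids has an ontology xref.
    """
    snomeds_by_code: dict[str, list[str]] = {}
    for entry in map_entries:
        if not entry.active:
            continue
        snomeds_by_code.setdefault(entry.icd10_code, []).append(entry.snomed_id)

    report = PivotCoverageReport()
    pairs: list[CandidatePair] = []
    seen_codes: set[str] = set()
    for code in codes:
        norm = code.normalized
        if norm in seen_codes:
            continue
        seen_codes.add(norm)
        report.n_inputs += 1
        snomeds = snomeds_by_code.get(norm)
        if not snomeds:
            report.n_unmatched_no_snomed += 1
            report.reason_by_code[norm] = REASON_NO_SNOMED
            continue
        targets: dict[str, str] = {}
        for sid in snomeds:
            for uri, label in xrefs.targets(sid):
                targets.setdefault(uri, label)
        if not targets:
            report.n_unmatched_no_xref += 1
            report.reason_by_code[norm] = REASON_NO_XREF
            continue
        report.n_matched += 1
        for uri in sorted(targets):
            pairs.append(
                CandidatePair(
                    source_id=norm,
                    source_text=code.raw,
                    target_uri=uri,
                    target_label=targets[uri],
                    method="snomed_pivot",
                )
            )
    pairs.sort(key=lambda p: (p.source_id, p.target_uri))
    report.validate()
    return pairs, report


def fanout_histogram(pairs: Iterable[CandidatePair]) -> FanoutHistogram:
    """Count distinct target concepts per source code over deduplicated pairs."""
    targets: dict[str, set[str]] = {}
    for pair in pairs:
        targets.setdefault(pair.source_id, set()).add(pair.target_uri)
    return FanoutHistogram(counts={code: len(t) for code, t in targets.items()})
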