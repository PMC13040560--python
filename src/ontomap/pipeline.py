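"""Run configuration and end-to-end orchestration of the two-step pipeline.

A run executes: ingest (ontologies, extended map, records) → candidate
generation (embedding retrieval, SNOMED pivot, or the union of both, with
method provenance preserved) → adjudication → summary reports.  All artifacts
are plain text (JSONL/JSON/CSV) and, with offline backends, a pure function
of (inputs, config, seed); a manifest records the config hash, the seed and a
content digest of every artifact.
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .adjudicate import (
    AdjudicationResult,
    AdjudicatorBackend,
    MockAdjudicator,
    RemoteChatAdjudicator,
    adjudicate,
)
from .candidates import (
    CandidatePair,
    InputRecord,
    fanout_histogram,
    generate_pivot_candidates,
    generate_rag_candidates,
)
from .embeddings import (
    EmbeddingBackend,
    HashedNgramEmbedder,
    RemoteEmbeddingBackend,
    build_index,
)
from .evaluate import acceptance_summary
from .ontology import harvest_xrefs, normalize_icd10, parse_extended_map, parse_obograph

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_records",
    "pairs_to_jsonl",
    "pairs_from_jsonl",
    "results_to_jsonl",
    "run_pipeline",
]

DEFAULT_XREF_PREFIXES = {"MONDO": "SCTID", "HP": "SNOMEDCT_US"}


class RunConfig(BaseModel):
    """Validated configuration for one pipeline run."""

    ontology_paths: list[str]
    target_prefixes: list[str] = ["MONDO", "HP"]
    xref_prefixes: dict[str, str] = Field(default_factory=lambda: dict(DEFAULT_XREF_PREFIXES))
    map_path: Optional[str] = None
    records_path: str
    generator: Literal["rag", "snomed_pivot", "both"] = "both"
    k: int = 3
    embedding_backend: Literal["hashed-ngram", "remote"] = "hashed-ngram"
    embedding_dimension: int = 512
    adjudicator: Literal["mock", "remote"] = "mock"
    prompt_template: str = "strict"
    accept_table_path: Optional[str] = None
    out_dir: str = "out"
    seed: int = 0
    log_level: str = "INFO"

    @field_validator("k")
    @classmethod
    def _k_positive(cls, v: int) -> int:
        if v < 1:
            raise ValueError("k must be >= 1")
        return v

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def make_embedding_backend(config: RunConfig) -> EmbeddingBackend:
    if config.embedding_backend == "hashed-ngram":
        return HashedNgramEmbedder(dimension=config.embedding_dimension, seed=config.seed)
    return RemoteEmbeddingBackend(dimension=config.embedding_dimension)


def make_adjudicator_backend(config: RunConfig) -> AdjudicatorBackend:
    if config.adjudicator == "mock":
        table = []
        if config.accept_table_path:
            df = pd.read_csv(config.accept_table_path, dtype=str)
            table = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
        return MockAdjudicator(accept_table=table)
    return RemoteChatAdjudicator()


def read_records(path: str | Path) -> list[InputRecord]:
    """Read input records from CSV/TSV with header (record_id, text[, icd10])."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if "record_id" not in df.columns or "text" not in df.columns:
        raise ValueError(f"records file {path} must have 'record_id' and 'text' columns")
    records = []
    for _, row in df.iterrows():
        code = row.get("icd10", "")
        records.append(
            InputRecord(
                record_id=str(row["record_id"]),
                text=str(row["text"]),
                icd10_code=normalize_icd10(code) if code and code.strip() else None,
            )
        )
    return records


def pairs_to_jsonl(pairs: list[CandidatePair]) -> str:
    lines = []
    for p in pairs:
        lines.append(
            json.dumps(
                {
                    "source_id": p.source_id,
                    "source_text": p.source_text,
                    "target_uri": p.target_uri,
                    "target_label": p.target_label,
                    "method": p.method,
                    "score": p.score,
                    "matched_text": p.matched_text,
                },
                sort_keys=True,
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


def pairs_from_jsonl(content: str) -> list[CandidatePair]:
    pairs = []
    for line in io.StringIO(content):
        if not line.strip():
            continue
        rec = json.loads(line)
        pairs.append(
            CandidatePair(
                source_id=rec["source_id"],
                source_text=rec["source_text"],
                target_uri=rec["target_uri"],
                target_label=rec["target_label"],
                method=rec["method"],
                score=rec.get("score"),
                matched_text=rec.get("matched_text"),
            )
        )
    return pairs


def results_to_jsonl(results: list[AdjudicationResult]) -> str:
    lines = []
    for r in results:
        lines.append(
            json.dumps(
                {
                    "source_id": r.pair.source_id,
                    "target_uri": r.pair.target_uri,
                    "method": r.pair.method,
                    "decision": r.decision,
                    "justification": r.justification,
                    "raw_response": r.raw_response,
                    "backend": r.backend_name,
                    "error": r.error,
                },
                sort_keys=True,
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured pipeline end to end; returns the artifact map.

    In ``both`` mode the candidate sets of the two generators are unioned
    (method provenance preserved) before adjudication.  Artifacts written to
    ``config.out_dir``: ``pairs.jsonl``, ``adjudications.jsonl``,
    ``coverage.json`` and ``fanout.json`` (pivot runs), ``summary.json`` and
    ``manifest.json``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    logger.info("stage=ingest ontologies=%d", len(config.ontology_paths))
    concepts = []
    for path in config.ontology_paths:
        concepts.extend(parse_obograph(Path(path), config.target_prefixes))
    if not concepts:
        raise RuntimeError("ingest produced no concepts")
    records = read_records(config.records_path)
    logger.info("stage=ingest concepts=%d records=%d", len(concepts), len(records))

    pairs: list[CandidatePair] = []
    coverage = None
    fanout = None

    if config.generator in ("rag", "both"):
        backend = make_embedding_backend(config)
        index = build_index(concepts, backend)
        rag_records = [r for r in records if r.text.strip()]
        rag_pairs = generate_rag_candidates(rag_records, index, backend, k=config.k)
        logger.info("stage=map-rag in=%d out=%d", len(rag_records), len(rag_pairs))
        pairs.extend(rag_pairs)

    if config.generator in ("snomed_pivot", "both"):
        if not config.map_path:
            raise RuntimeError("snomed_pivot generator requires map_path")
        map_entries = parse_extended_map(Path(config.map_path))
        xrefs = harvest_xrefs(concepts, config.xref_prefixes)
        codes = []
        seen = set()
        for r in records:
            if r.icd10_code and r.icd10_code.normalized not in seen:
                seen.add(r.icd10_code.normalized)
                codes.append(r.icd10_code)
        pivot_pairs, coverage = generate_pivot_candidates(codes, map_entries, xrefs)
        fanout = fanout_histogram(pivot_pairs)
        logger.info(
            "stage=map-pivot in=%d out=%d matched=%d no_snomed=%d no_xref=%d",
            coverage.n_inputs,
            len(pivot_pairs),
            coverage.n_matched,
            coverage.n_unmatched_no_snomed,
            coverage.n_unmatched_no_xref,
        )
        pairs.extend(pivot_pairs)

    pairs.sort(key=lambda p: (p.source_id, p.method, p.target_uri))

    adj_backend = make_adjudicator_backend(config)
    results = adjudicate(pairs, adj_backend, template=config.prompt_template)
    logger.info(
        "stage=adjudicate in=%d accepted=%d",
        len(results),
        sum(1 for r in results if r.decision == "accept"),
    )

    summary: dict = {"n_pairs": len(pairs), "by_method": {}}
    for method in ("rag", "snomed_pivot"):
        sub = [r for r in results if r.pair.method == method]
        if sub:
            summary["by_method"][method] = acceptance_summary(sub).to_dict()
    if results:
        summary["overall"] = acceptance_summary(results).to_dict()

    artifacts: dict[str, Path] = {}

    def write(name: str, content: str) -> None:
        p = out_dir / name
        p.write_text(content)
        artifacts[name] = p

    write("pairs.jsonl", pairs_to_jsonl(pairs))
    write("adjudications.jsonl", results_to_jsonl(results))
    if coverage is not None:
        write("coverage.json", json.dumps(coverage.to_dict(), indent=1, sort_keys=True) + "\n")
    if fanout is not None:
        write("fanout.json", json.dumps(fanout.to_dict(), indent=1, sort_keys=True) + "\n")
    write("summary.json", json.dumps(summary, indent=1, sort_keys=True) + "\n")

    manifest = {
        "config_hash": config.config_hash(),
        "config": config.model_dump(),
        "seed": config.seed,
        "version": __version__,
        "artifacts": {name: _digest(path) for name, path in sorted(artifacts.items())},
    }
    write("manifest.json", json.dumps(manifest, indent=1, sort_keys=True) + "\n")

    return {
        "pairs": pairs,
        "results": results,
        "coverage": coverage,
        "fanout": fanout,
        "summary": summary,
        "artifacts": artifacts,
    }
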