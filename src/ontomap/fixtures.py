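"""Synthetic miniature fixtures: toy ontologies, SNOMED maps and records.

Everything the pipeline ingests can be generated here at desk scale, with
planted ground truth, so every stage is testable without downloading real
MONDO/HPO releases or the SNOMED CT extended map.  Fixtures are emitted in
the exact external formats the parsers accept (OBO-graph JSON, RF2 or
two-column TSV, records CSV), so parser tests and pipeline tests share one
source of truth.

The generator is fully deterministic under a fixed seed (byte-identical
output), and its ground truth is constructed directly from the planted
structure — never by running the pipeline — so end-to-end tests compare two
independent routes to the same answer.  Labels are combinatorial phrases from
a bundled word list; fixtures exercise structure, not clinical semantics.
"""

from __future__ import annotations

import io
import json
import random
from dataclasses import dataclass, field
from typing import Optional

__all__ = ["FixtureSpec", "ToyWorld", "make_toy_ontology", "make_toy_map_and_records"]

_ADJECTIVES = [
    "chronic", "acute", "congenital", "familial", "juvenile", "recurrent",
    "severe", "mild", "progressive", "transient", "atypical", "isolated",
    "neonatal", "late-onset", "early-onset", "bilateral",
]
_SITES = [
    "renal", "hepatic", "cardiac", "pulmonary", "cerebral", "ocular",
    "skeletal", "cutaneous", "intestinal", "vascular", "auditory", "spinal",
    "pancreatic", "thyroid", "muscular", "articular",
]
_KINDS = [
    "dysplasia", "syndrome", "malformation", "deficiency", "atrophy",
    "stenosis", "hyperplasia", "agenesis", "fibrosis", "anomaly",
    "hypoplasia", "degeneration",
]
_FILLER = [
    "observation", "episode", "finding", "status", "assessment", "screening",
    "history", "exposure",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Size and coverage knobs for one synthetic world; seed is mandatory."""

    seed: int
    n_mondo: int = 8
    n_hp: int = 5
    max_synonyms: int = 2
    n_snomed: int = 30
    xref_coverage: float = 0.8
    map_coverage: float = 0.8
    n_records: int = 12
    exact_match_fraction: float = 0.6
    n_reason_i: int = 2  # codes absent from the extended map
    n_reason_ii: int = 2  # codes mapped only to snomed ids without xrefs

    def __post_init__(self):
        for name in ("xref_coverage", "map_coverage", "exact_match_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class ToyWorld:
    """Fully materialized synthetic world (internal to the generator)."""

    concepts: list[dict]  # {concept_id, uri, label, synonyms, xrefs}
    snomed_pool: list[str]
    map_rows: list[tuple[str, str, bool]]  # (snomed_id, raw icd code, active)
    codes: dict[str, str]  # normalized -> raw
    records: list[dict]  # {record_id, text, icd10}
    ground_truth: list[dict] = field(default_factory=list)
    reason_i_codes: list[str] = field(default_factory=list)
    reason_ii_codes: list[str] = field(default_factory=list)


def _unique_labels(rng: random.Random, n: int) -> list[str]:
    labels: list[str] = []
    seen: set[str] = set()
    while len(labels) < n:
        lbl = f"{rng.choice(_ADJECTIVES)} {rng.choice(_SITES)} {rng.choice(_KINDS)}"
        if lbl not in seen:
            seen.add(lbl)
            labels.append(lbl)
    return labels


def _synonyms(rng: random.Random, label: str, n: int) -> list[str]:
    """Deterministic perturbations: word swaps and abbreviations."""
    words = label.split()
    variants = [
        f"{words[1]} {words[0]} {words[2]}",  # adjective/site swap
        f"{words[0][:4]}. {words[1]} {words[2]}",  # abbreviated adjective
        f"{label}, unspecified",
        f"{words[1]} {words[2]}",
    ]
    rng.shuffle(variants)
    out: list[str] = []
    for v in variants:
        if v != label and v not in out:
            out.append(v)
        if len(out) == n:
            break
    return out


def _make_codes(rng: random.Random, n: int) -> list[str]:
    codes: list[str] = []
    seen: set[str] = set()
    while len(codes) < n:
        raw = f"{rng.choice('ABDEGIJKNPQ')}{rng.randrange(10, 100)}.{rng.randrange(10)}"
        if raw not in seen:
            seen.add(raw)
            codes.append(raw)
    return codes


def build_world(spec: FixtureSpec) -> ToyWorld:
    """Construct the full synthetic world deterministically from the seed."""
    rng = random.Random(spec.seed)

    # --- concepts with labels and synonyms -------------------------------
    labels = _unique_labels(rng, spec.n_mondo + spec.n_hp)
    concepts: list[dict] = []
    for i in range(spec.n_mondo):
        cid = f"MONDO_{i + 1:07d}"
        concepts.append(
            {
                "concept_id": cid,
                "uri": f"http://purl.obolibrary.org/obo/{cid}",
                "label": labels[i],
                "synonyms": _synonyms(rng, labels[i], rng.randrange(spec.max_synonyms + 1)),
                "xrefs": [],
            }
        )
    for j in range(spec.n_hp):
        cid = f"HP_{j + 1:07d}"
        lbl = labels[spec.n_mondo + j]
        concepts.append(
            {
                "concept_id": cid,
                "uri": f"http://purl.obolibrary.org/obo/{cid}",
                "label": lbl,
                "synonyms": _synonyms(rng, lbl, rng.randrange(spec.max_synonyms + 1)),
                "xrefs": [],
            }
        )

    # --- SNOMED pool and xref assignment ---------------------------------
    snomed_pool = [str(10000000 + 13 * i) for i in range(spec.n_snomed)]
    n_xref = round(spec.xref_coverage * len(concepts))
    xref_concepts = concepts[:n_xref]
    # leave a reserve of snomed ids with no xref for reason-(ii) planting
    assignable = snomed_pool[: max(0, spec.n_snomed - spec.n_reason_ii)]
    xref_snomeds: list[str] = []
    for idx, concept in enumerate(xref_concepts):
        if not assignable:
            break
        sid = assignable[idx % len(assignable)]
        pfx = "SCTID" if concept["concept_id"].startswith("MONDO") else "SNOMEDCT_US"
        concept["xrefs"].append(f"{pfx}:{sid}")
        xref_snomeds.append(sid)
    xref_snomeds = sorted(set(xref_snomeds), key=snomed_pool.index)
    no_xref_snomeds = [s for s in snomed_pool if s not in set(xref_snomeds)]

    # --- extended-map rows and planted codes ------------------------------
    n_mapped = max(1, round(spec.map_coverage * len(xref_snomeds))) if xref_snomeds else 0
    mapped_snomeds = xref_snomeds[:n_mapped]
    n_matched_codes = max(1, (n_mapped + 1) // 2) if n_mapped else 0
    all_codes = _make_codes(
        rng, n_matched_codes + spec.n_reason_i + spec.n_reason_ii
    )
    matched_codes = all_codes[:n_matched_codes]
    reason_i_codes = all_codes[n_matched_codes : n_matched_codes + spec.n_reason_i]
    reason_ii_codes = all_codes[n_matched_codes + spec.n_reason_i :]

    map_rows: list[tuple[str, str, bool]] = []
    for i, sid in enumerate(mapped_snomeds):
        map_rows.append((sid, matched_codes[i % n_matched_codes], True))
    for i, code in enumerate(reason_ii_codes):
        if no_xref_snomeds:
            map_rows.append((no_xref_snomeds[i % len(no_xref_snomeds)], code, True))
    # superseded rows: inactive, must be ignored by the parser
    if mapped_snomeds and reason_i_codes:
        map_rows.append((mapped_snomeds[0], reason_i_codes[0], False))

    def norm(code: str) -> str:
        return code.upper().replace(".", "")

    codes = {norm(c): c for c in all_codes}

    # --- ground truth for the pivot join (constructed, not joined) -------
    targets_by_snomed: dict[str, list[str]] = {}
    for concept in concepts:
        for xref in concept["xrefs"]:
            sid = xref.split(":", 1)[1]
            targets_by_snomed.setdefault(sid, []).append(concept["concept_id"])
    label_by_id = {c["concept_id"]: c["label"] for c in concepts}
    ground_truth: list[dict] = []
    for code in matched_codes:
        uris = sorted(
            {
                uri
                for sid, c, active in map_rows
                if active and c == code
                for uri in targets_by_snomed.get(sid, [])
            }
        )
        for uri in uris:
            ground_truth.append(
                {
                    "kind": "pivot",
                    "code": norm(code),
                    "code_raw": code,
                    "target_uri": uri,
                    "target_label": label_by_id[uri],
                }
            )

    # --- records with planted exact-label matches -------------------------
    records: list[dict] = []
    n_exact = round(spec.exact_match_fraction * spec.n_records)
    code_cycle = all_codes or [""]
    for r in range(spec.n_records):
        rid = f"rec{r + 1:03d}"
        icd = code_cycle[r % len(code_cycle)]
        if r < n_exact:
            concept = concepts[r % len(concepts)]
            text = concept["label"]
            ground_truth.append(
                {
                    "kind": "rag",
                    "record_id": rid,
                    "text": text,
                    "target_uri": concept["concept_id"],
                    "target_label": concept["label"],
                }
            )
        else:
            text = (
                f"unrelated {rng.choice(_FILLER)} {rng.choice(_FILLER)} {r + 1}"
            )
        records.append({"record_id": rid, "text": text, "icd10": icd})

    return ToyWorld(
        concepts=concepts,
        snomed_pool=snomed_pool,
        map_rows=map_rows,
        codes=codes,
        records=records,
        ground_truth=ground_truth,
        reason_i_codes=[norm(c) for c in reason_i_codes],
        reason_ii_codes=[norm(c) for c in reason_ii_codes],
    )


def make_toy_ontology(spec: FixtureSpec) -> str:
    """Emit the world's concepts as an OBO-graph JSON document string.

    Round-trips losslessly through the OBO-graph parser; byte-identical for
    equal specs.
    """
    world = build_world(spec)
    nodes = []
    for c in world.concepts:
        meta: dict = {}
        if c["synonyms"]:
            meta["synonyms"] = [{"pred": "hasExactSynonym", "val": s} for s in c["synonyms"]]
        if c["xrefs"]:
            meta["xrefs"] = [{"val": x} for x in c["xrefs"]]
        node = {"id": c["uri"], "lbl": c["label"], "type": "CLASS"}
        if meta:
            node["meta"] = meta
        nodes.append(node)
    doc = {"graphs": [{"id": "toy-ontology", "nodes": nodes, "edges": []}]}
    return json.dumps(doc, indent=1)


def make_toy_map_and_records(
    spec: FixtureSpec, dialect: str = "rf2"
) -> tuple[str, str, list[dict]]:
    """Emit the extended-map table, the records CSV and the ground truth.

    ``dialect`` selects the map layout: ``"rf2"`` (full refset header with
    active flags, including planted inactive rows) or ``"minimal"``
    (two-column TSV, active rows only).  Ground truth lists every (code,
    concept) pair derivable by the pivot join plus one entry per record whose
    text was planted as an exact concept label.
    """
    world = build_world(spec)

    buf = io.StringIO()
    if dialect == "rf2":
        buf.write(
            "id\teffectiveTime\tactive\tmoduleId\trefsetId\treferencedComponentId\tmapTarget\n"
        )
        for i, (sid, code, active) in enumerate(world.map_rows):
            buf.write(
                f"row{i:04d}\t20240101\t{1 if active else 0}\t900000000000207008\t"
                f"447562003\t{sid}\t{code}\n"
            )
    elif dialect == "minimal":
        buf.write("snomed_id\ticd10_code\n")
        for sid, code, active in world.map_rows:
            if active:
                buf.write(f"{sid}\t{code}\n")
    else:
        raise ValueError(f"unknown map dialect {dialect!r}")
    map_tsv = buf.getvalue()

    rec_buf = io.StringIO()
    rec_buf.write("record_id,text,icd10\n")
    for rec in world.records:
        rec_buf.write(f"{rec['record_id']},\"{rec['text']}\",{rec['icd10']}\n")
    records_csv = rec_buf.getvalue()

    return map_tsv, records_csv, list(world.ground_truth)
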