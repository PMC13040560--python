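"""Parsing of OBO-graph ontology documents and SNOMED CT → ICD-10 extended maps.

Target ontologies (MONDO, HPO) ship as OBO-graph JSON: a ``graphs`` list whose
``nodes`` carry an identifier (a full URI such as
``http://purl.obolibrary.org/obo/MONDO_0000001``), a primary label ``lbl`` and,
under ``meta``, synonym and cross-reference records.  Only identifiers, labels,
synonyms and xrefs are used; definitions, descriptions and hierarchical edges
are deliberately ignored.

The SNOMED CT extended map is the official RF2 refset table linking SNOMED
concept identifiers (``referencedComponentId``) to ICD-10 targets
(``mapTarget``).  A minimal two-column TSV dialect (snomed_id, icd10_code) is
also accepted so small fixtures need not mimic the full RF2 header.
"""

from __future__ import annotations

import io
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OntologyConcept",
    "XrefTable",
    "SnomedIcdMapEntry",
    "CodeString",
    "ObographParseError",
    "ExtendedMapFormatError",
    "parse_obograph",
    "harvest_xrefs",
    "normalize_icd10",
    "parse_extended_map",
]


class ObographParseError(ValueError):
    """Raised when an OBO-graph document is structurally malformed."""


class ExtendedMapFormatError(ValueError):
    """Raised when an extended-map table has an unrecognizable header."""


# Characters stripped from ICD-10 codes besides the decimal point: whitespace,
# the dagger/asterisk etiology-manifestation marks, and hyphen placeholders.
DEFAULT_AUXILIARY_CHARS = ".†*-"

_WS_RE = re.compile(r"\s+")


@dataclass(frozen=True)
class CodeString:
    """An ICD-10 code in raw and normalized form."""

    raw: str
    normalized: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.normalized


@dataclass(frozen=True)
class OntologyConcept:
    """One controlled-vocabulary term: id, label, synonyms, cross-references.

    ``concept_id`` is the compact prefixed identifier (``MONDO_0000001``,
    ``HP_0000118``); ``uri`` retains the identifier exactly as found in the
    source document for traceability.
    """

    concept_id: str
    uri: str
    label: str
    synonyms: tuple[str, ...] = ()
    xrefs: tuple[tuple[str, str], ...] = ()

    @property
    def prefix(self) -> str:
        """Ontology prefix, e.g. ``MONDO`` or ``HP``."""
        return self.concept_id.split("_", 1)[0]

    @property
    def terms(self) -> tuple[str, ...]:
        """Primary label followed by synonyms — the strings to be embedded."""
        return (self.label, *self.synonyms)


@dataclass
class XrefTable:
    """Lookup from SNOMED identifier to (concept id, clinical label) targets."""

    entries: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    n_skipped: int = 0

    def __contains__(self, snomed_id: str) -> bool:
        return snomed_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def targets(self, snomed_id: str) -> list[tuple[str, str]]:
        return self.entries.get(snomed_id, [])


@dataclass(frozen=True)
class SnomedIcdMapEntry:
    """One active row of the SNOMED→ICD-10 extended map, code normalized."""

    snomed_id: str
    icd10_code: str
    active: bool = True


def normalize_icd10(code: str, auxiliary_chars: str = DEFAULT_AUXILIARY_CHARS) -> CodeString:
    """Normalize an ICD-10 code for cross-system comparison.

    Uppercases and removes the decimal point plus auxiliary characters
    (whitespace, dagger ``†``, asterisk ``*``, hyphen placeholders), so e.g.
    ``"Q87.8"`` → ``"Q878"``.  The transformation is idempotent.

    Raises
    ------
    ValueError
        If the code is empty or blank.
    """
    if code is None or not code.strip():
        raise ValueError("ICD-10 code is empty or blank")
    raw = code
    out = _WS_RE.sub("", code.upper())
    for ch in auxiliary_chars:
        out = out.replace(ch, "")
    if not out:
        raise ValueError(f"ICD-10 code {code!r} is empty after normalization")
    return CodeString(raw=raw, normalized=out)


def _compact_id(uri: str) -> str:
    """Compact prefixed id from a node identifier (last URI path segment)."""
    tail = uri.rstrip("/").rsplit("/", 1)[-1]
    # OBO-graph ids occasionally appear in CURIE form MONDO:0000001.
    return tail.replace(":", "_")


def _load_document(document: Union[str, Path, Mapping]) -> Mapping:
    if isinstance(document, Mapping):
        return document
    if isinstance(document, Path):
        return json.loads(document.read_text())
    text = str(document)
    if text.lstrip().startswith("{"):
        return json.loads(text)
    return json.loads(Path(text).read_text())


def parse_obograph(
    document: Union[str, Path, Mapping],
    target_prefixes: Sequence[str],
) -> list[OntologyConcept]:
    """Extract concepts with a target prefix from an OBO-graph JSON document.

    Parameters
    ----------
    document : dict, JSON string, or path
        OBO-graph content with ``graphs[*].nodes``.
    target_prefixes : sequence of str
        Ontology prefixes to retain, e.g. ``("MONDO", "HP")``.  A trailing
        underscore is accepted and ignored.

    Returns
    -------
    list of OntologyConcept
        Exactly the nodes whose compact identifier carries a target prefix,
        each with its primary label, deduplicated synonyms and raw xrefs.
        Nodes lacking a label are skipped with a warning (real releases
        contain obsolete stubs).  Definitions and edges are ignored.
    """
    if not target_prefixes:
        raise ValueError("target_prefixes must be non-empty")
    prefixes = tuple(p.rstrip("_") for p in target_prefixes)

    doc = _load_document(document)
    graphs = doc.get("graphs")
    if not isinstance(graphs, list):
        raise ObographParseError("document has no 'graphs' list")

    concepts: list[OntologyConcept] = []
    for graph in graphs:
        nodes = graph.get("nodes")
        if nodes is None:
            raise ObographParseError("graph has no 'nodes' list")
        for node in nodes:
            if not isinstance(node, Mapping) or "id" not in node:
                raise ObographParseError(f"malformed node (missing 'id'): {node!r}")
            uri = str(node["id"])
            cid = _compact_id(uri)
            if cid.split("_", 1)[0] not in prefixes:
                continue
            label = node.get("lbl")
            if not label:
                logger.warning("node %s has no label; skipped", uri)
                continue
            meta = node.get("meta") or {}
            synonyms: list[str] = []
            seen = {label}
            for syn in meta.get("synonyms", []) or []:
                val = syn.get("val") if isinstance(syn, Mapping) else None
                if val and val not in seen:
                    synonyms.append(val)
                    seen.add(val)
            xrefs: list[tuple[str, str]] = []
            for xref in meta.get("xrefs", []) or []:
                val = xref.get("val") if isinstance(xref, Mapping) else None
                if val and ":" in val:
                    pfx, _, rest = val.partition(":")
                    xrefs.append((pfx, rest))
            concepts.append(
                OntologyConcept(
                    concept_id=cid,
                    uri=uri,
                    label=str(label),
                    synonyms=tuple(synonyms),
                    xrefs=tuple(xrefs),
                )
            )
    return concepts


def harvest_xrefs(
    concepts: Iterable[OntologyConcept],
    prefix_by_source: Mapping[str, str],
) -> XrefTable:
    """Compile SNOMED cross-references into a SNOMED-id → concept lookup.

    ``prefix_by_source`` maps each ontology prefix to the xref prefix that
    denotes SNOMED identifiers in that ontology — conventionally ``SCTID``
    for MONDO and ``SNOMEDCT_US`` for HPO.  Xrefs with any other prefix are
    skipped silently and tallied in ``XrefTable.n_skipped``.

    Targets are stored under the compact concept id (``MONDO_…``/``HP_…``) —
    the same identifier form used in vector-index payloads — so candidates
    from both generators share one identifier space.
    """
    table = XrefTable()
    for concept in concepts:
        try:
            wanted = prefix_by_source[concept.prefix]
        except KeyError:
            raise ValueError(
                f"no xref prefix configured for ontology prefix {concept.prefix!r}"
            ) from None
        for pfx, value in concept.xrefs:
            if pfx != wanted:
                table.n_skipped += 1
                continue
            snomed_id = value.strip()
            if not snomed_id.isdigit():
                table.n_skipped += 1
                continue
            table.entries.setdefault(snomed_id, []).append((concept.concept_id, concept.label))
    return table


_RF2_REQUIRED = ("referencedComponentId", "mapTarget")


def parse_extended_map(table: Union[str, Path]) -> list[SnomedIcdMapEntry]:
    """Parse a SNOMED→ICD-10 extended map into normalized entries.

    Accepts the RF2 refset dialect (header with ``referencedComponentId`` and
    ``mapTarget``; rows with ``active != 1`` or an empty target are dropped)
    or a minimal two-column TSV ``snomed_id<TAB>icd10_code`` with or without a
    header row.  Every returned ``icd10_code`` is normalized.
    """
    if isinstance(table, Path) or (isinstance(table, str) and "\t" not in table and "\n" not in table):
        content = Path(table).read_text()
    else:
        content = str(table)

    df = pd.read_csv(io.StringIO(content), sep="\t", dtype=str, header=None, keep_default_na=False)
    if df.empty:
        return []

    first = [str(v) for v in df.iloc[0].tolist()]
    if all(col in first for col in _RF2_REQUIRED):
        df.columns = first
        df = df.iloc[1:]
        if "active" in df.columns:
            df = df[df["active"] == "1"]
        sn_col, tgt_col = _RF2_REQUIRED
    elif df.shape[1] == 2:
        # minimal dialect; drop a header row if the first column is not an id
        if not first[0].isdigit():
            df = df.iloc[1:]
        df.columns = ["snomed_id", "icd10_code"]
        sn_col, tgt_col = "snomed_id", "icd10_code"
    else:
        raise ExtendedMapFormatError(
            "unrecognizable extended-map header: expected RF2 columns "
            f"{_RF2_REQUIRED} or a two-column (snomed_id, icd10_code) table; "
            f"got {first}"
        )

    entries: list[SnomedIcdMapEntry] = []
    for sn, tgt in zip(df[sn_col], df[tgt_col]):
        sn = str(sn).strip()
        tgt = str(tgt).strip()
        if not sn or not tgt:
            continue
        entries.append(
            SnomedIcdMapEntry(
                snomed_id=sn,
                icd10_code=normalize_icd10(tgt).normalized,
                active=True,
            )
        )
    return entries
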