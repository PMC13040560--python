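"""Candidate generation: RAG retrieval, SNOMED pivot join, fan-out stats."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ontomap.candidates import (
    REASON_NO_SNOMED,
    REASON_NO_XREF,
    CandidatePair,
    InputRecord,
    fanout_histogram,
    generate_pivot_candidates,
    generate_rag_candidates,
)
from ontomap.embeddings import HashedNgramEmbedder, build_index
from ontomap.ontology import CodeString, OntologyConcept, SnomedIcdMapEntry, XrefTable


def nested_loop_join(codes, map_entries, xrefs: XrefTable) -> set[tuple[str, str]]:
    """Independent oracle: brute-force nested-loop join, set semantics."""
    out = set()
    for code in codes:
        for entry in map_entries:
            if entry.active and entry.icd10_code == code.normalized:
                for uri, _ in xrefs.targets(entry.snomed_id):
                    out.add((code.normalized, uri))
    return out


def _concept(cid, label, synonyms=()):
    return OntologyConcept(
        concept_id=cid,
        uri=f"http://purl.obolibrary.org/obo/{cid}",
        label=label,
        synonyms=tuple(synonyms),
    )


def _code(raw: str) -> CodeString:
    return CodeString(raw=raw, normalized=raw.upper().replace(".", ""))


class TestGenerateRagCandidates:
    BACKEND = HashedNgramEmbedder(dimension=64)

    def _index(self, concepts):
        return build_index(concepts, self.BACKEND)

    def test_exact_label_record_scores_one(self):
        concepts = [_concept("MONDO_0000001", "renal agenesis"), _concept("HP_0000001", "apnea")]
        index = self._index(concepts)
        records = [InputRecord(record_id="r1", text="apnea")]
        pairs = generate_rag_candidates(records, index, self.BACKEND, k=1)
        assert len(pairs) == 1
        assert pairs[0].target_uri == "HP_0000001"
        assert pairs[0].score == pytest.approx(1.0)
        assert pairs[0].method == "rag"
        assert pairs[0].matched_text == "apnea"

    def test_synonym_hits_collapse_to_concept_with_primary_label(self):
        concepts = [_concept("MONDO_0000001", "anemia", synonyms=["anaemia", "low hemoglobin"])]
        index = self._index(concepts)
        pairs = generate_rag_candidates(
            [InputRecord(record_id="r1", text="anaemia")], index, self.BACKEND, k=3
        )
        # three term hits, one concept: exactly one pair, best-matching synonym kept
        assert len(pairs) == 1
        assert pairs[0].matched_text == "anaemia"
        assert pairs[0].target_label == "anemia"
        assert pairs[0].score == pytest.approx(1.0)

    def test_at_most_k_pairs_per_record_and_urls_in_index(self):
        concepts = [_concept(f"MONDO_{i:07d}", f"disorder type {i}", [f"syn {i}"]) for i in range(6)]
        index = self._index(concepts)
        records = [InputRecord(record_id=f"r{j}", text=f"disorder type {j}") for j in range(4)]
        pairs = generate_rag_candidates(records, index, self.BACKEND, k=3)
        urls = {url for _, url in index.payloads}
        per_record: dict[str, int] = {}
        for p in pairs:
            per_record[p.source_id] = per_record.get(p.source_id, 0) + 1
            assert p.target_uri in urls
        assert all(n <= 3 for n in per_record.values())

    def test_matches_per_record_full_scan_concept_oracle(self):
        rng = random.Random(11)
        concepts = [
            _concept(f"MONDO_{i:07d}", f"{rng.choice('abcdef')} condition {i}", [f"variant {i}"])
            for i in range(5)
        ]
        index = self._index(concepts)
        records = [
            InputRecord(record_id="r1", text="a condition 1"),
            InputRecord(record_id="r2", text="variant 4"),
        ]
        k = 3
        pairs = generate_rag_candidates(records, index, self.BACKEND, k=k)
        for record in records:
            q = self.BACKEND.embed(record.text)
            # oracle: best score per concept over all its terms, then top-k concepts
            best: dict[str, float] = {}
            for entry in index.entries:
                s = float(entry.vector @ q)
                best[entry.payload_url] = max(s, best.get(entry.payload_url, -2.0))
            expected = sorted(best, key=lambda u: (-best[u], u))[:k]
            got = [p.target_uri for p in pairs if p.source_id == record.record_id]
            assert got == expected

    def test_empty_text_records_skipped(self, caplog):
        concepts = [_concept("MONDO_0000001", "anemia")]
        index = self._index(concepts)
        records = [
            InputRecord(record_id="r1", text="anemia"),
            InputRecord(record_id="r2", text=" ", icd10_code=_code("Q87.8")),
        ]
        with caplog.at_level("WARNING"):
            pairs = generate_rag_candidates(records, index, self.BACKEND, k=1)
        assert {p.source_id for p in pairs} == {"r1"}
        assert "r2" in caplog.text

    def test_rag_pair_requires_score(self):
        with pytest.raises(ValueError):
            CandidatePair(
                source_id="r1",
                source_text="x",
                target_uri="MONDO_0000001",
                target_label="y",
                method="rag",
            )


def _random_pivot_instance(rng: random.Random):
    n_codes = rng.randint(1, 50)
    n_snomed = rng.randint(1, 50)
    n_concepts = rng.randint(1, 40)
    codes = [_code(f"{rng.choice('ABQ')}{i:02d}.{rng.randrange(10)}") for i in range(n_codes)]
    snomeds = [str(1000 + i) for i in range(n_snomed)]
    map_entries = [
        SnomedIcdMapEntry(
            snomed_id=rng.choice(snomeds),
            icd10_code=rng.choice(codes).normalized,
            active=rng.random() < 0.9,
        )
        for _ in range(rng.randint(0, 120))
    ]
    xrefs = XrefTable()
    for _ in range(rng.randint(0, 80)):
        sid = rng.choice(snomeds)
        cid = f"MONDO_{rng.randrange(n_concepts):07d}"
        if (cid, f"label {cid}") not in xrefs.targets(sid):
            xrefs.entries.setdefault(sid, []).append((cid, f"label {cid}"))
    return codes, map_entries, xrefs


class TestGeneratePivotCandidates:
    def test_single_join_path(self):
        map_entries = [SnomedIcdMapEntry(snomed_id="S1", icd10_code="Q878")]
        xrefs = XrefTable(entries={"S1": [("MONDO_0019755", "malformation syndrome")]})
        pairs, report = generate_pivot_candidates([_code("Q87.8")], map_entries, xrefs)
        assert [(p.source_id, p.target_uri) for p in pairs] == [("Q878", "MONDO_0019755")]
        assert pairs[0].method == "snomed_pivot"
        assert pairs[0].target_label == "malformation syndrome"
        assert report.n_matched == 1 and report.n_inputs == 1

    def test_reason_classification(self):
        map_entries = [SnomedIcdMapEntry(snomed_id="S1", icd10_code="Q878")]
        xrefs = XrefTable(entries={"S2": [("MONDO_0000001", "x")]})
        codes = [_code("A00"), _code("Q87.8")]
        pairs, report = generate_pivot_candidates(codes, map_entries, xrefs)
        assert pairs == []
        assert report.reason_by_code == {
            "A00": REASON_NO_SNOMED,
            "Q878": REASON_NO_XREF,
        }
        report.validate()

    def test_empty_inputs_consistent_report(self):
        pairs, report = generate_pivot_candidates([], [], XrefTable())
        assert pairs == [] and report.n_inputs == 0
        report.validate()

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_nested_loop_oracle(self, seed):
        rng = random.Random(seed)
        codes, map_entries, xrefs = _random_pivot_instance(rng)
        pairs, report = generate_pivot_candidates(codes, map_entries, xrefs)
        got = {(p.source_id, p.target_uri) for p in pairs}
        assert got == nested_loop_join(codes, map_entries, xrefs)
        assert len(got) == len(pairs)  # deduplicated
        report.validate()
        assert report.n_inputs == len({c.normalized for c in codes})

    def test_generation_is_idempotent_and_stably_ordered(self):
        rng = random.Random(3)
        codes, map_entries, xrefs = _random_pivot_instance(rng)
        first, _ = generate_pivot_candidates(codes, map_entries, xrefs)
        second, _ = generate_pivot_candidates(codes, map_entries, xrefs)
        assert first == second
        keys = [(p.source_id, p.target_uri) for p in first]
        assert keys == sorted(keys)


class TestFanoutHistogram:
    def _pair(self, code, uri):
        return CandidatePair(
            source_id=code, source_text=code, target_uri=uri, target_label=uri,
            method="snomed_pivot",
        )

    def test_distinct_target_counts(self):
        pairs = [self._pair("A", "x"), self._pair("A", "y"), self._pair("B", "x")]
        hist = fanout_histogram(pairs)
        assert hist.counts == {"A": 2, "B": 1}
        assert hist.total_pairs == 3

    def test_empty_input(self):
        hist = fanout_histogram([])
        assert hist.counts == {}
        assert hist.share_at_or_above(10) == 0.0

    def test_large_fanout_entry(self):
        pairs = [self._pair("Q878", f"MONDO_{i:07d}") for i in range(329)]
        hist = fanout_histogram(pairs)
        assert hist.counts["Q878"] == 329
        assert hist.share_at_or_above(10) == 1.0
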