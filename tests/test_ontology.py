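"""Ontology document parsing, xref harvesting and ICD-10 normalization."""

import json

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ontomap.ontology import (
    ExtendedMapFormatError,
    ObographParseError,
    harvest_xrefs,
    normalize_icd10,
    parse_extended_map,
    parse_obograph,
)

OBO = "http://purl.obolibrary.org/obo"


def _doc(nodes):
    return {"graphs": [{"nodes": nodes, "edges": []}]}


class TestParseObograph:
    def test_prefix_filter_and_fields(self):
        doc = _doc(
            [
                {
                    "id": f"{OBO}/MONDO_0000001",
                    "lbl": "disease",
                    "meta": {"synonyms": [{"val": "condition"}]},
                },
                {"id": f"{OBO}/HP_0000118", "lbl": "Phenotypic abnormality"},
                {"id": f"{OBO}/CHEBI_00001", "lbl": "molecule"},
            ]
        )
        concepts = parse_obograph(doc, ["MONDO", "HP"])
        assert [c.concept_id for c in concepts] == ["MONDO_0000001", "HP_0000118"]
        assert concepts[0].label == "disease"
        assert concepts[0].synonyms == ("condition",)
        assert concepts[1].synonyms == ()

    def test_synonym_dedup_drops_duplicates_and_label(self):
        doc = _doc(
            [
                {
                    "id": f"{OBO}/MONDO_0000002",
                    "lbl": "disease",
                    "meta": {"synonyms": [{"val": "X"}, {"val": "X"}, {"val": "disease"}]},
                }
            ]
        )
        (concept,) = parse_obograph(doc, ["MONDO"])
        assert concept.synonyms == ("X",)

    def test_unlabelled_node_skipped_with_warning(self, caplog):
        doc = _doc([{"id": f"{OBO}/MONDO_0000003"}])
        with caplog.at_level("WARNING"):
            assert parse_obograph(doc, ["MONDO"]) == []
        assert "MONDO_0000003" in caplog.text

    def test_malformed_node_raises_naming_offender(self):
        doc = _doc([{"lbl": "no id here"}])
        with pytest.raises(ObographParseError, match="no id here"):
            parse_obograph(doc, ["MONDO"])

    def test_accepts_json_string_input(self):
        doc = json.dumps(_doc([{"id": f"{OBO}/HP_0000001", "lbl": "All"}]))
        (concept,) = parse_obograph(doc, ["HP"])
        assert concept.uri.endswith("HP_0000001")

    @given(st.lists(st.sampled_from(["MONDO", "HP", "CHEBI", "UBERON"]), min_size=1, max_size=8))
    def test_never_returns_foreign_prefixes(self, prefixes):
        nodes = [
            {"id": f"{OBO}/{p}_{i:07d}", "lbl": f"term {i}"} for i, p in enumerate(prefixes)
        ]
        concepts = parse_obograph(_doc(nodes), ["MONDO", "HP"])
        assert all(c.prefix in ("MONDO", "HP") for c in concepts)
        assert len(concepts) == sum(1 for p in prefixes if p in ("MONDO", "HP"))


class TestHarvestXrefs:
    PREFIX_MAP = {"MONDO": "SCTID", "HP": "SNOMEDCT_US"}

    def _concepts(self, xrefs_by_id):
        nodes = [
            {"id": f"{OBO}/{cid}", "lbl": f"label {cid}", "meta": {"xrefs": [{"val": x} for x in xs]}}
            for cid, xs in xrefs_by_id.items()
        ]
        return parse_obograph(_doc(nodes), ["MONDO", "HP"])

    def test_configured_prefixes_harvested(self):
        concepts = self._concepts(
            {
                "MONDO_0000001": ["SCTID:44054006"],
                "HP_0000118": ["SNOMEDCT_US:73211009"],
            }
        )
        table = harvest_xrefs(concepts, self.PREFIX_MAP)
        assert table.targets("44054006") == [("MONDO_0000001", "label MONDO_0000001")]
        assert table.targets("73211009") == [("HP_0000118", "label HP_0000118")]

    def test_other_prefixes_skipped_and_counted(self):
        concepts = self._concepts({"MONDO_0000001": ["ICD10:Q87.8", "UMLS:C012345"]})
        table = harvest_xrefs(concepts, self.PREFIX_MAP)
        assert len(table) == 0
        assert table.n_skipped == 2

    def test_wrong_ontology_snomed_prefix_is_skipped(self):
        # SNOMEDCT_US on a MONDO concept does not match MONDO's configured SCTID
        concepts = self._concepts({"MONDO_0000001": ["SNOMEDCT_US:1234"]})
        assert len(harvest_xrefs(concepts, self.PREFIX_MAP)) == 0

    def test_unconfigured_ontology_prefix_raises(self):
        concepts = self._concepts({"MONDO_0000001": ["SCTID:1"]})
        with pytest.raises(ValueError, match="MONDO"):
            harvest_xrefs(concepts, {"HP": "SNOMEDCT_US"})

    def test_referential_integrity(self, fixture_spec):
        from ontomap.fixtures import make_toy_ontology

        concepts = parse_obograph(make_toy_ontology(fixture_spec), ["MONDO", "HP"])
        table = harvest_xrefs(concepts, self.PREFIX_MAP)
        known = {c.concept_id for c in concepts}
        for targets in table.entries.values():
            assert all(cid in known for cid, _ in targets)
        assert all(sid.isdigit() for sid in table.entries)


class TestNormalizeIcd10:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("Q87.8", "Q878"),
            ("q87.8 ", "Q878"),
            ("Q878", "Q878"),
            ("E11.9†", "E119"),
            ("A52.7*", "A527"),
            ("M10.-", "M10"),
            (" b 20 ", "B20"),
        ],
    )
    def test_examples(self, raw, expected):
        assert normalize_icd10(raw).normalized == expected

    @pytest.mark.parametrize("bad", ["", "   ", "\t"])
    def test_blank_rejected(self, bad):
        with pytest.raises(ValueError):
            normalize_icd10(bad)

    @given(
        st.text(
            alphabet="ABQEMabq0123456789.†*- \t",
            min_size=1,
            max_size=12,
        ).filter(lambda s: any(ch.isalnum() for ch in s))
    )
    def test_idempotent_on_code_like_strings(self, raw):
        once = normalize_icd10(raw).normalized
        assert normalize_icd10(once).normalized == once
        assert "." not in once and " " not in once
        assert once == once.upper()


class TestParseExtendedMap:
    RF2_HEADER = "id\teffectiveTime\tactive\tmoduleId\trefsetId\treferencedComponentId\tmapTarget"

    def test_rf2_rows_parsed_and_normalized(self):
        table = "\n".join(
            [
                self.RF2_HEADER,
                "r1\t20240101\t1\tm\trs\t44054006\tE11.9",
                "r2\t20240101\t0\tm\trs\t44054006\tE10.9",
                "r3\t20240101\t1\tm\trs\t73211009\t",
            ]
        )
        entries = parse_extended_map(table)
        assert [(e.snomed_id, e.icd10_code) for e in entries] == [("44054006", "E119")]

    def test_minimal_two_column_dialect(self):
        entries = parse_extended_map("snomed_id\ticd10\n123\tQ87.8\n")
        assert [(e.snomed_id, e.icd10_code) for e in entries] == [("123", "Q878")]

    def test_minimal_dialect_without_header(self):
        entries = parse_extended_map("123\tQ87.8\n456\tA00\n")
        assert [(e.snomed_id, e.icd10_code) for e in entries] == [
            ("123", "Q878"),
            ("456", "A00"),
        ]

    def test_unrecognizable_header_lists_expected_columns(self):
        with pytest.raises(ExtendedMapFormatError, match="referencedComponentId"):
            parse_extended_map("a\tb\tc\n1\t2\t3\n")

    def test_output_codes_are_normalization_fixed_points(self, toy_world_dir):
        entries = parse_extended_map(toy_world_dir / "map.tsv")
        assert entries
        for e in entries:
            assert normalize_icd10(e.icd10_code).normalized == e.icd10_code
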