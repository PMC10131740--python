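"""Mapping stage: registry composition, id minting, row->resource rules."""

import json
import logging
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tabfhir import (
    Mapper,
    coding_system_uri,
    default_registry,
    make_reference,
    make_resource_id,
    resource_type_for,
)
from tabfhir.errors import IdentityError, UnknownTableError, UnknownVocabularyError
from tabfhir.paths import get_path
from tabfhir.schemas import CORE_EVENT_TABLES

TABLE_TO_RESOURCE = {
    "patients": "Patient",
    "admissions": "Encounter",
    "transfers": "Encounter",
    "chartevents": "Observation",
    "labevents": "Observation",
    "procedureevents": "Procedure",
    "prescriptions": "MedicationRequest",
    "inputevents": "MedicationAdministration",
    "microbiologyevents": "Observation",
    "outputevents": "Observation",
    "procedures_icd": "Procedure",
    "diagnoses_icd": "Condition",
}


class TestRegistry:
    @pytest.mark.parametrize("table,resource", sorted(TABLE_TO_RESOURCE.items()))
    def test_table_resource_assignment(self, registry, table, resource):
        assert resource_type_for(registry, table) == resource

    def test_composition_counts(self, registry):
        counts = Counter(registry.table_to_resource.values())
        assert counts == {
            "Observation": 4, "Encounter": 2, "Procedure": 2, "Patient": 1,
            "Condition": 1, "MedicationRequest": 1, "MedicationAdministration": 1,
        }
        assert len(registry.table_to_resource) == 12

    def test_reference_tables_are_not_mapped(self, registry):
        with pytest.raises(UnknownTableError):
            resource_type_for(registry, "d_icd_diagnoses")

    def test_every_rule_belongs_to_a_registered_table(self, registry):
        for name, tm in registry.tables.items():
            assert name in registry.table_to_resource
            for rule in tm.rules:
                assert rule.source_table == name
                assert rule.element_path
                assert "[" not in rule.element_path


class TestResourceIds:
    def test_deterministic(self):
        a = make_resource_id("diagnoses_icd", (10, 20, "A011", 9))
        b = make_resource_id("diagnoses_icd", (10, 20, "A011", 9))
        assert a == b

    def test_documented_pattern(self):
        rid = make_resource_id("diagnoses_icd", (10, 20, "A011", 9))
        assert rid == "diagnoses.icd-10-20-A011-9"

    def test_null_key_component_is_identity_error(self):
        with pytest.raises(IdentityError):
            make_resource_id("patients", (None,))

    def test_long_ids_hash_down_to_fhir_limit(self):
        rid = make_resource_id("chartevents", ["x" * 100, "y" * 100])
        assert len(rid) <= 64
        assert rid == make_resource_id("chartevents", ["x" * 100, "y" * 100])

    def test_no_collisions_across_cohort_diagnoses(self, cohort):
        rows = list(cohort.tables["diagnoses_icd"].rows())
        ids = {
            make_resource_id("diagnoses_icd",
                             (r["subject_id"], r["hadm_id"], r["seq_num"])): r
            for r in rows
        }
        assert len(ids) == len(rows)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 10**9), st.text(
        alphabet="abcdefghij _/|", min_size=1, max_size=12)), min_size=1, max_size=30,
        unique=True))
    def test_distinct_key_tuples_mint_distinct_ids(self, keys):
        ids = {make_resource_id("t", list(k)) for k in keys}
        assert len(ids) == len(keys)


class TestReferences:
    def test_patient_reference_matches_minted_patient_id(self):
        ref = make_reference("Patient", 10)
        assert ref == {"reference": f"Patient/{make_resource_id('patients', [10])}"}

    def test_encounter_reference_resolves_via_admissions_recipe(self):
        ref = make_reference("Encounter", 20)
        assert ref == {"reference": f"Encounter/{make_resource_id('admissions', [20])}"}

    def test_null_raw_id_is_identity_error(self):
        with pytest.raises(IdentityError):
            make_reference("Patient", None)


class TestCodingSystems:
    @pytest.mark.parametrize("kind,version,expect_fragment", [
        ("icd_diagnoses", 9, "icd-9-cm"),
        ("icd_diagnoses", 10, "icd-10-cm"),
        ("icd_procedures", 9, "icd-9-cm"),
        ("icd_procedures", 10, "ICD10"),
    ])
    def test_icd_system_uris(self, kind, version, expect_fragment):
        assert expect_fragment in coding_system_uri(kind, version)

    def test_local_items_uri_is_configurable(self):
        assert coding_system_uri("local_items", local_system_uri="urn:x") == "urn:x"

    def test_unknown_vocabulary_is_lookup_error(self):
        with pytest.raises(UnknownVocabularyError):
            coding_system_uri("snomed", 1)


class TestDiagnosisMapping:
    """The published diagnosis mapping: six elements of Condition."""

    def test_all_six_elements_populated(self, diagnosis_row):
        res = Mapper().map_row("diagnoses_icd", diagnosis_row)
        assert res.resource_type == "Condition"
        assert get_path(res.body, "subject.reference") == "Patient/patients-10"
        assert get_path(res.body, "encounter.reference") == "Encounter/admissions-20"
        assert get_path(res.body, "code.coding.code") == "A011"
        assert get_path(res.body, "code.coding.version") == "9"
        assert get_path(res.body, "code.coding.display") == "Paratyphoid fever A"
        assert get_path(res.body, "code.text") == "Paratyphoid fever A"

    def test_title_duplicated_into_display_and_text(self, diagnosis_row):
        res = Mapper().map_row("diagnoses_icd", diagnosis_row)
        assert get_path(res.body, "code.coding.display") == get_path(res.body, "code.text")

    def test_system_uri_tracks_icd_version(self, diagnosis_row):
        body9 = Mapper().map_row("diagnoses_icd", diagnosis_row).body
        diagnosis_row["icd_version"] = 10
        body10 = Mapper().map_row("diagnoses_icd", diagnosis_row).body
        assert get_path(body9, "code.coding.system") == "http://hl7.org/fhir/sid/icd-9-cm"
        assert get_path(body10, "code.coding.system") == "http://hl7.org/fhir/sid/icd-10-cm"

    def test_null_title_elides_display_and_text(self, diagnosis_row):
        diagnosis_row["long_title"] = None
        body = Mapper().map_row("diagnoses_icd", diagnosis_row).body
        assert get_path(body, "code.coding.display") is None
        assert get_path(body, "code.text") is None
        assert get_path(body, "code.coding.code") == "A011"

    def test_unmapped_extra_column_excluded_and_logged_once(self, diagnosis_row, caplog):
        mapper = Mapper()
        with_extra = dict(diagnosis_row, mystery_column="x")
        with caplog.at_level(logging.WARNING, logger="tabfhir.mapping"):
            a = mapper.map_row("diagnoses_icd", with_extra)
            b = mapper.map_row("diagnoses_icd", with_extra)
        plain = Mapper().map_row("diagnoses_icd", diagnosis_row)
        assert a.body == plain.body == b.body
        hits = [r for r in caplog.records if "mystery_column" in r.message]
        assert len(hits) == 1  # once per run, not per row

    def test_missing_primary_key_value_is_identity_error(self, diagnosis_row):
        diagnosis_row["hadm_id"] = None
        with pytest.raises(IdentityError):
            Mapper().map_row("diagnoses_icd", diagnosis_row)


class TestMapTable:
    def test_zero_row_table_maps_to_empty(self, cohort):
        from tabfhir.schemas import SourceTable

        empty = SourceTable(cohort.tables["patients"].schema,
                            cohort.tables["patients"].frame.iloc[0:0])
        assert Mapper().map_table(empty) == []

    def test_one_resource_per_row_in_order(self, joined_tables, mapped):
        for name in CORE_EVENT_TABLES:
            assert len(mapped[name]) == joined_tables[name].n_rows, name

    def test_admissions_and_transfers_both_become_encounters(self, mapped):
        for name in ("admissions", "transfers"):
            assert {r.resource_type for r in mapped[name]} == {"Encounter"}

    def test_mapping_is_deterministic_bytewise(self, joined_tables):
        a = Mapper().map_table(joined_tables["diagnoses_icd"])
        b = Mapper().map_table(joined_tables["diagnoses_icd"])
        assert [json.dumps(x.body) for x in a] == [json.dumps(x.body) for x in b]


class TestValueConservation:
    """Brute-force oracle: per (row, rule), direct lookup == engine output."""

    def test_every_ruled_value_lands_at_its_path(self, joined_tables, registry):
        mapper = Mapper()
        checked = 0
        for name in CORE_EVENT_TABLES:
            tm = registry.tables[name]
            for row in joined_tables[name].rows():
                resource = mapper.map_row(name, row)
                for rule in tm.rules:
                    raw = row.get(rule.source_column)
                    if raw is None:
                        continue
                    expected = mapper.transform_value(rule.transform, raw, name)
                    got = get_path(resource.body, rule.element_path)
                    assert got == expected, (name, rule.element_path, row)
                    checked += 1
        assert checked > 1000

    def test_referential_closure(self, mapped, all_resources):
        """Every emitted reference points at an id minted in the same run."""
        minted = {f"{r.resource_type}/{r.id}" for r in all_resources}

        def walk(node):
            if isinstance(node, dict):
                for k, v in node.items():
                    if k == "reference":
                        yield v
                    else:
                        yield from walk(v)
            elif isinstance(node, list):
                for v in node:
                    yield from walk(v)

        refs = {ref for r in all_resources for ref in walk(r.body)}
        assert refs
        assert refs <= minted
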