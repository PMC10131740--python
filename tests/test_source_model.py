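"""Query stage: schemas, CSV reading, dictionary joins, patient batching."""

import logging

import pandas as pd
import pytest

from tabfhir import (
    ColumnSpec,
    QueryBatch,
    SourceTable,
    TableSchema,
    join_reference,
    query_batch,
    read_table,
    write_table,
)
from tabfhir.errors import (
    ParseError,
    SchemaError,
    TableIntegrityError,
    UnknownTableError,
)
from tabfhir.schemas import (
    CORE_EVENT_TABLES,
    REFERENCE_TABLES,
    ReferenceJoin,
    schema_from_dict,
    schemas_to_json,
)

EXPECTED_JOINS = {
    "chartevents": ("d_items", ("itemid",)),
    "labevents": ("d_labitems", ("itemid",)),
    "procedureevents": ("d_items", ("itemid",)),
    "inputevents": ("d_items", ("itemid",)),
    "outputevents": ("d_items", ("itemid",)),
    "procedures_icd": ("d_icd_procedures", ("icd_code", "icd_version")),
    "diagnoses_icd": ("d_icd_diagnoses", ("icd_code", "icd_version")),
}
NO_JOIN = ("patients", "admissions", "transfers", "prescriptions", "microbiologyevents")


class TestDefaultSchemas:
    def test_sixteen_tables_registered(self, schemas):
        assert len(schemas) == 16
        assert set(CORE_EVENT_TABLES) | set(REFERENCE_TABLES) == set(schemas)

    @pytest.mark.parametrize("table,expected", sorted(EXPECTED_JOINS.items()))
    def test_event_dictionary_pairings(self, schemas, table, expected):
        rj = schemas[table].reference_join
        assert (rj.reference_table, rj.join_key) == expected

    @pytest.mark.parametrize("table", NO_JOIN)
    def test_core_tables_have_no_dictionary(self, schemas, table):
        assert schemas[table].reference_join is None

    def test_primary_keys_are_declared_non_nullable_columns(self, schemas):
        for schema in schemas.values():
            assert schema.primary_key
            for pk in schema.primary_key:
                assert not schema.column(pk).nullable

    def test_reference_joins_point_at_registered_tables(self, schemas):
        for schema in schemas.values():
            if schema.reference_join:
                assert schema.reference_join.reference_table in schemas

    def test_schema_registry_serializes_and_round_trips(self, schemas):
        import json

        doc = json.loads(schemas_to_json(schemas))
        assert set(doc) == set(schemas)
        assert schema_from_dict(doc["diagnoses_icd"]) == schemas["diagnoses_icd"]

    def test_pk_must_exist_and_be_non_nullable(self):
        with pytest.raises(SchemaError):
            TableSchema("t", (ColumnSpec("a", "integer", nullable=True),), ("a",))
        with pytest.raises(SchemaError):
            TableSchema("t", (ColumnSpec("a", "integer"),), ("b",))


class TestReadTable:
    def test_header_only_csv_yields_zero_rows(self, tmp_path, schemas):
        p = tmp_path / "diagnoses_icd.csv"
        p.write_text("subject_id,hadm_id,seq_num,icd_code,icd_version\n")
        tab = read_table(p, schemas["diagnoses_icd"])
        assert tab.n_rows == 0

    def test_reads_fixture_rows(self, tmp_path, schemas):
        p = tmp_path / "diagnoses_icd.csv"
        p.write_text(
            "subject_id,hadm_id,seq_num,icd_code,icd_version\n"
            "1,2,1,A011,10\n1,2,2,I10,10\n1,3,1,4019,9\n"
        )
        tab = read_table(p, schemas["diagnoses_icd"])
        assert tab.n_rows == 3
        first = next(tab.rows())
        assert first == {"subject_id": 1, "hadm_id": 2, "seq_num": 1,
                         "icd_code": "A011", "icd_version": 10}

    def test_missing_required_column_is_schema_error(self, tmp_path, schemas):
        p = tmp_path / "diagnoses_icd.csv"
        p.write_text("subject_id,hadm_id,seq_num,icd_version\n1,2,1,10\n")
        with pytest.raises(SchemaError, match="icd_code"):
            read_table(p, schemas["diagnoses_icd"])

    def test_duplicate_primary_key_is_integrity_error(self, tmp_path, schemas):
        p = tmp_path / "diagnoses_icd.csv"
        p.write_text(
            "subject_id,hadm_id,seq_num,icd_code,icd_version\n1,2,1,A011,10\n1,2,1,I10,10\n"
        )
        with pytest.raises(TableIntegrityError):
            read_table(p, schemas["diagnoses_icd"])

    def test_unparseable_non_nullable_cell_aborts_with_location(self, tmp_path, schemas):
        p = tmp_path / "diagnoses_icd.csv"
        p.write_text("subject_id,hadm_id,seq_num,icd_code,icd_version\nx,2,1,A011,10\n")
        with pytest.raises(ParseError, match="subject_id"):
            read_table(p, schemas["diagnoses_icd"])

    def test_unparseable_nullable_cell_becomes_null_with_warning(self, tmp_path, schemas, caplog):
        p = tmp_path / "labevents.csv"
        p.write_text(
            "labevent_id,subject_id,hadm_id,itemid,charttime,valuenum,valueuom\n"
            "1,1,2,50912,2021-01-01 10:00:00,oops,mg/dL\n"
        )
        with caplog.at_level(logging.WARNING, logger="tabfhir.source"):
            tab = read_table(p, schemas["labevents"])
        assert next(tab.rows())["valuenum"] is None
        assert any("valuenum" in r.message for r in caplog.records)

    @pytest.mark.parametrize("gz", [False, True])
    def test_write_read_round_trip_every_cohort_table(self, cohort, tmp_path, gz):
        for name, tab in cohort.tables.items():
            path = tmp_path / f"{name}.csv{'.gz' if gz else ''}"
            write_table(tab, path)
            back = read_table(path, tab.schema)
            assert back.equals(tab), name


class TestJoinReference:
    def test_dictionary_title_lands_on_event_row(self, schemas):
        ev = SourceTable(schemas["diagnoses_icd"], pd.DataFrame([
            {"subject_id": 1, "hadm_id": 2, "seq_num": 1, "icd_code": "A011", "icd_version": 9},
        ]).astype({"subject_id": "Int64", "hadm_id": "Int64", "seq_num": "Int64", "icd_version": "Int64"}))
        ref = SourceTable(schemas["d_icd_diagnoses"], pd.DataFrame([
            {"icd_code": "A011", "icd_version": 9, "long_title": "Paratyphoid fever A"},
        ]).astype({"icd_version": "Int64"}))
        joined = next(join_reference(ev, ref).rows())
        assert joined["long_title"] == "Paratyphoid fever A"
        assert joined["icd_code"] == "A011"

    def test_empty_dictionary_keeps_rows_nulls_and_warns(self, cohort, schemas, caplog):
        ev = cohort.tables["diagnoses_icd"]
        empty_ref = SourceTable(
            schemas["d_icd_diagnoses"],
            cohort.tables["d_icd_diagnoses"].frame.iloc[0:0],
        )
        with caplog.at_level(logging.WARNING, logger="tabfhir.source"):
            joined = join_reference(ev, empty_ref)
        assert joined.n_rows == ev.n_rows
        assert joined.frame["long_title"].isna().all()
        assert len([r for r in caplog.records if "dictionary entry" in r.message]) == ev.n_rows

    def test_join_preserves_row_count_and_event_values(self, cohort):
        for name in ("labevents", "chartevents", "diagnoses_icd", "procedures_icd",
                     "inputevents", "outputevents", "procedureevents"):
            ev = cohort.tables[name]
            ref = cohort.tables[ev.schema.reference_join.reference_table]
            joined = join_reference(ev, ref)
            assert joined.n_rows == ev.n_rows
            for col in ev.schema.column_names:
                assert joined.frame[col].equals(ev.frame[col]), (name, col)

    def test_wrong_reference_table_is_schema_error(self, cohort):
        with pytest.raises(SchemaError):
            join_reference(cohort.tables["diagnoses_icd"], cohort.tables["d_labitems"])


class TestQueryBatch:
    def test_single_subject_filters_every_event_table(self, cohort):
        subject = int(cohort.tables["patients"].frame["subject_id"].iloc[0])
        out = query_batch(cohort.tables, QueryBatch(frozenset({subject})))
        for name, tab in out.items():
            if "subject_id" in tab.schema.column_names:
                assert set(tab.frame["subject_id"].dropna()) <= {subject}, name

    def test_all_subjects_is_identity(self, cohort):
        subjects = frozenset(int(s) for s in cohort.tables["patients"].frame["subject_id"])
        out = query_batch(cohort.tables, QueryBatch(subjects))
        for name, tab in out.items():
            assert tab.n_rows == cohort.tables[name].n_rows

    def test_reference_tables_pass_through(self, cohort):
        subject = int(cohort.tables["patients"].frame["subject_id"].iloc[0])
        out = query_batch(cohort.tables, QueryBatch(frozenset({subject})))
        assert out["d_icd_diagnoses"].n_rows == cohort.tables["d_icd_diagnoses"].n_rows

    def test_partition_conserves_rows(self, cohort):
        subjects = sorted(int(s) for s in cohort.tables["patients"].frame["subject_id"])
        half = len(subjects) // 2
        b1 = query_batch(cohort.tables, QueryBatch(frozenset(subjects[:half])))
        b2 = query_batch(cohort.tables, QueryBatch(frozenset(subjects[half:])))
        for name, tab in cohort.tables.items():
            if "subject_id" not in tab.schema.column_names:
                continue
            assert b1[name].n_rows + b2[name].n_rows == tab.n_rows, name

    def test_empty_batch_rejected(self):
        with pytest.raises(SchemaError):
            QueryBatch(frozenset())

    def test_unknown_table_is_lookup_error(self, cohort):
        subject = int(cohort.tables["patients"].frame["subject_id"].iloc[0])
        with pytest.raises(UnknownTableError):
            query_batch(cohort.tables, QueryBatch(frozenset({subject}), tables=("nope",)))
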