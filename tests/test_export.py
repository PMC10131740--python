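"""Flat 4-key export and the long->wide feature-matrix pivot."""

import json
import logging

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tabfhir import (
    ExportConfig,
    FlatRecord,
    check_flat_dict,
    default_extraction_rules,
    export_json,
    flat_record_schema,
    flatten_resource,
    pivot_records,
    read_flat_json,
    select_records,
)
from tabfhir.errors import ConfigurationError, ExportError
from tabfhir.mapping import FhirResource


def _observation(rid="obs-1", text="Blood pressure", value=114.0, unit="mmHg"):
    return FhirResource("Observation", rid, {
        "resourceType": "Observation", "id": rid, "status": "final",
        "code": {"coding": [{"code": "220179", "display": text}], "text": text},
        "subject": {"reference": "Patient/patients-1"},
        "encounter": {"reference": "Encounter/admissions-2"},
        "effectiveDateTime": "2021-01-01T10:00:00+00:00",
        "valueQuantity": {"value": value, "unit": unit},
    })


@pytest.fixture(scope="module")
def rules():
    return default_extraction_rules()


class TestFlattenResource:
    def test_blood_pressure_observation_flattens_to_4_keys(self, rules):
        recs = flatten_resource(_observation(), rules["Observation"])
        assert len(recs) == 1
        d = recs[0].to_dict()
        assert d["feature_name"] == "Blood pressure"
        assert d["table_name"] == "observation"
        assert d["value"] == 114
        assert d["metadata"]["unit"] == "mmHg"
        assert d["metadata"]["resource_id"] == "obs-1"
        assert check_flat_dict(d) == []

    def test_feature_name_prefers_text_over_display(self, rules):
        res = _observation()
        res.body["code"]["coding"][0]["display"] = "BP systolic (local display)"
        rec = flatten_resource(res, rules["Observation"])[0]
        assert rec.feature_name == "Blood pressure"

    def test_condition_flattens_title_as_feature_code_as_value(self, mapped, rules):
        condition = mapped["diagnoses_icd"][0]
        rec = flatten_resource(condition, rules["Condition"])[0]
        assert rec.table_name == "condition"
        assert rec.feature_name == condition.body["code"]["text"]
        assert rec.value == condition.body["code"]["coding"][0]["code"]
        assert rec.metadata["coding_system"] == condition.body["code"]["coding"][0]["system"]
        assert rec.metadata["resource_id"] == condition.id

    def test_value_paths_all_missing_yields_null_value_logged(self, rules, caplog):
        res = _observation()
        del res.body["valueQuantity"]
        with caplog.at_level(logging.WARNING, logger="tabfhir.flat"):
            rec = flatten_resource(res, rules["Observation"])[0]
        assert rec.value is None
        assert any("null value" in r.message for r in caplog.records)

    def test_unresolvable_feature_name_is_export_error(self, rules):
        res = _observation()
        del res.body["code"]
        res.body["valueString"] = "x"
        with pytest.raises(ExportError, match="obs-1"):
            flatten_resource(res, rules["Observation"])

    def test_multi_component_observation_yields_one_record_per_component(self, rules):
        res = _observation()
        res.body["component"] = [
            {"code": {"text": "Systolic"}, "valueQuantity": {"value": 120.0, "unit": "mmHg"}},
            {"code": {"text": "Diastolic"}, "valueQuantity": {"value": 80.0, "unit": "mmHg"}},
        ]
        recs = flatten_resource(res, rules["Observation"])
        assert [r.feature_name for r in recs] == ["Blood pressure", "Systolic", "Diastolic"]
        assert [r.value for r in recs] == [114.0, 120.0, 80.0]
        assert all(r.metadata["resource_id"] == "obs-1" for r in recs)


class TestSelectRecords:
    def test_table_selector_filters(self, run_env, rules):
        _config, _report, store = run_env
        recs = select_records(store, ExportConfig(tables=("condition",)), rules)
        assert recs
        assert {r.table_name for r in recs} == {"condition"}

    def test_empty_config_selects_every_flattenable_resource(self, run_env, rules):
        _config, _report, store = run_env
        recs = select_records(store, ExportConfig(), rules)
        expected = sum(
            len(flatten_resource(r, rules[r.resource_type]))
            for r in store.iter_all() if r.resource_type in rules
        )
        assert len(recs) == expected

    def test_selection_is_a_filter_of_select_all(self, run_env, rules):
        _config, _report, store = run_env
        everything = [json.dumps(r.to_dict(), sort_keys=True)
                      for r in select_records(store, ExportConfig(), rules)]
        some = [json.dumps(r.to_dict(), sort_keys=True)
                for r in select_records(store, ExportConfig(tables=("observation", "condition")), rules)]
        pool = list(everything)
        for s in some:
            pool.remove(s)  # raises if not a sub-multiset

    def test_feature_selector_matches_linear_scan(self, run_env, rules):
        _config, _report, store = run_env
        everything = select_records(store, ExportConfig(), rules)
        target = everything[0].feature_name
        got = select_records(store, ExportConfig(features=(target,)), rules)
        assert len(got) == sum(1 for r in everything if r.feature_name == target)
        assert all(r.feature_name == target for r in got)

    def test_metadata_whitelist_trims(self, run_env, rules):
        _config, _report, store = run_env
        recs = select_records(
            store, ExportConfig(metadata_labels=("subject_ref",)), rules
        )
        assert all(set(r.metadata) <= {"subject_ref"} for r in recs)

    def test_unknown_table_selector_warns_and_contributes_nothing(self, run_env, rules, caplog):
        _config, _report, store = run_env
        with caplog.at_level(logging.WARNING, logger="tabfhir.flat"):
            recs = select_records(store, ExportConfig(tables=("martian",)), rules)
        assert recs == []
        assert any("unknown table" in r.message for r in caplog.records)


class TestExportJson:
    def test_empty_record_list_writes_empty_array(self, tmp_path):
        p = export_json([], tmp_path / "out.json")
        assert json.loads(p.read_text()) == []

    @pytest.mark.parametrize("ndjson", [False, True])
    def test_write_read_round_trip(self, run_env, rules, tmp_path, ndjson):
        _config, _report, store = run_env
        recs = select_records(store, ExportConfig(), rules)
        p = export_json(recs, tmp_path / "out.json", ndjson=ndjson)
        back = read_flat_json(p, ndjson=ndjson)
        assert back == recs

    def test_every_exported_object_has_exactly_four_keys(self, run_env, rules, tmp_path):
        _config, _report, store = run_env
        recs = select_records(store, ExportConfig(), rules)
        p = export_json(recs, tmp_path / "out.json")
        objs = json.loads(p.read_text())
        schema = flat_record_schema()
        assert set(schema["required"]) == {"feature_name", "table_name", "value", "metadata"}
        assert schema["additionalProperties"] is False
        for obj in objs:
            assert set(obj) == {"feature_name", "table_name", "value", "metadata"}
            assert check_flat_dict(obj) == []


def _rec(subject, feature, value, encounter=None):
    meta = {"subject_ref": subject, "resource_id": "x"}
    if encounter:
        meta["encounter_ref"] = encounter
    return FlatRecord(feature, "condition", value, meta)


class TestPivot:
    def test_binary_presence_two_by_two(self):
        recs = [
            _rec("A", "X", "c1"), _rec("A", "Y", "c2"), _rec("B", "X", "c1"),
        ]
        table = pivot_records(recs, aggregation="presence")
        assert table.feature_names == ["X", "Y"]
        assert table.frame.values.tolist() == [[1, 1], [1, 0]]

    def test_empty_records_yield_empty_table(self):
        table = pivot_records([], aggregation="presence")
        assert table.n_rows == 0 and table.feature_names == []

    def test_mean_aggregation_matches_groupby_oracle(self):
        recs = [
            _rec("A", "hr", 60.0), _rec("A", "hr", 80.0),
            _rec("A", "rr", 12.0), _rec("B", "hr", 100.0),
        ]
        table = pivot_records(recs, aggregation="mean")
        oracle = (
            pd.DataFrame([{"s": r.metadata["subject_ref"], "f": r.feature_name,
                           "v": r.value} for r in recs])
            .groupby(["s", "f"])["v"].mean()
        )
        assert table.frame.loc["A", "hr"] == oracle[("A", "hr")] == 70.0
        assert table.frame.loc["B", "hr"] == 100.0
        assert pd.isna(table.frame.loc["B", "rr"])  # explicit missing, not zero

    def test_last_by_insertion_order(self):
        recs = [_rec("A", "hr", 60.0), _rec("A", "hr", 80.0)]
        table = pivot_records(recs, aggregation="last")
        assert table.frame.loc["A", "hr"] == 80.0

    def test_record_without_subject_is_skipped_with_warning(self, caplog):
        orphan = FlatRecord("X", "condition", "c", {"resource_id": "x"})
        with caplog.at_level(logging.WARNING, logger="tabfhir.flat"):
            table = pivot_records([orphan, _rec("A", "X", "c")])
        assert table.n_rows == 1
        assert any("lacks a subject" in r.message for r in caplog.records)

    def test_presence_conservation(self, run_env):
        _config, _report, store = run_env
        recs = select_records(store, ExportConfig(tables=("condition",)))
        table = pivot_records(recs, aggregation="presence")
        distinct_pairs = {(r.metadata["subject_ref"], r.feature_name) for r in recs}
        assert int(table.frame.to_numpy().sum()) == len(distinct_pairs)

    def test_subject_encounter_index_policy(self):
        recs = [_rec("A", "X", "c", encounter="E1"), _rec("A", "X", "c", encounter="E2")]
        table = pivot_records(recs, index_policy="subject_encounter")
        assert table.n_rows == 2

    def test_unknown_policy_or_aggregation_rejected(self):
        with pytest.raises(ConfigurationError):
            pivot_records([], index_policy="hospital")
        with pytest.raises(ConfigurationError):
            pivot_records([], aggregation="median")

    def test_feature_table_csv_round_trip(self, tmp_path):
        table = pivot_records([_rec("A", "X", "c")], aggregation="presence")
        p = table.to_csv(tmp_path / "wide.csv")
        back = pd.read_csv(p, index_col=0)
        assert back.loc["A", "X"] == 1

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(
        st.tuples(st.sampled_from(["A", "B", "C"]), st.sampled_from(["f1", "f2", "f3"]),
                  st.floats(-1e6, 1e6)),
        min_size=1, max_size=25,
    ))
    def test_mean_pivot_agrees_with_brute_force(self, triples):
        recs = [_rec(s, f, v) for s, f, v in triples]
        table = pivot_records(recs, aggregation="mean")
        df = pd.DataFrame([{"s": s, "f": f, "v": v} for s, f, v in triples])
        oracle = df.groupby(["s", "f"])["v"].mean()
        for (s, f), expect in oracle.items():
            assert table.frame.loc[s, f] == pytest.approx(expect)
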