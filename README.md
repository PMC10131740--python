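# tabfhir

Harmonize relational hospital tables into validated FHIR R4 resources and
flat, analysis-ready records.

Electronic health records live in hospital-specific relational schemas;
machine-learning tooling wants flat tables. `tabfhir` bridges the two with a
five-stage extract-transform-load pipeline over MIMIC-IV-shaped CSV tables
(core tables: `patients`, `admissions`, `transfers`; event tables such as
`labevents`, `chartevents`, `diagnoses_icd`; reference dictionaries such as
`d_icd_diagnoses`):

1. **query** — read the tables and left-join each event table with its
   reference dictionary (e.g. `diagnoses_icd` ⋈ `d_icd_diagnoses` on
   `(icd_code, icd_version)`), optionally in patient batches;
2. **map** — translate each row into one FHIR R4 *core* resource through a
   declarative registry. Twelve tables map onto seven resource types
   (4 → `Observation`, 2 → `Encounter`, 2 → `Procedure`, 1 each →
   `Patient`, `Condition`, `MedicationRequest`, `MedicationAdministration`);
   an ICD diagnosis row lands in
   `Condition.code.coding[0].{code,version,display}` with the full title
   duplicated into `coding[0].display` and `code.text`;
3. **validate** — syntactic validation (data types, required elements,
   hierarchy, cardinality, dateTime lexical + calendar form) against
   shipped R4-core profiles; failing resources are rejected and logged,
   never stored, and never abort the run;
4. **load** — idempotent upsert into a patient-model document store (one
   JSON document per resource, grouped by type; SQLite or plain-directory
   backend);
5. **export** — flatten each stored resource into records with exactly four
   keys — `feature_name`, `table_name`, `value`, `metadata` — where the
   feature name comes from the code's `text` element (stable across coding
   systems, unlike `display`). A long→wide pivot turns the records into a
   subject × feature matrix (binary presence for coded diagnoses, mean or
   last value for numeric features).

A deterministic synthetic cohort generator emits all sixteen tables with
referentially consistent keys (plus optional defect injection: malformed
dates, nulled required fields, missing dictionary entries), so the whole
pipeline is testable without access to real patient data.

## Worked example

```bash
tabfhir generate --patients 10 --seed 7 --out-dir cohort/
tabfhir run --input-dir cohort/ --store store.db --export-out export.json
```

The run prints its counters:

```json
{
  "rows_read": 492,
  "resources_mapped": 492,
  "accepted": 492,
  "rejected": 0,
  "stored": 492,
  "records_exported": 482
}
```

All 492 source rows became resources, every resource passed syntactic
validation (a clean cohort rejects nothing), and 482 flat records were
exported — `Patient` resources carry identity only and are not flattened
(492 − 10 patients = 482). One exported diagnosis record:

```json
{
  "feature_name": "Gastro-esophageal reflux disease without esophagitis",
  "table_name": "condition",
  "value": "K219",
  "metadata": {
    "resource_id": "diagnoses.icd-10000-2000001-1",
    "subject_ref": "Patient/patients-10000",
    "encounter_ref": "Encounter/admissions-2000001",
    "coding_system": "http://hl7.org/fhir/sid/icd-10-cm",
    "coding_version": "10"
  }
}
```

The human-readable title is the feature name, the ICD-10 code is the value,
and the metadata carries the references and coding-system detail needed for
cohort building. From Python the same run is:

```python
from tabfhir import CohortSpec, RunConfig, generate_to_dir, run_pipeline

generate_to_dir(CohortSpec(n_patients=10, seed=7), "cohort/")
report = run_pipeline(RunConfig(input_dir="cohort/", store_path="store.db"))
print(report.counters)
```

and pivoting the export into a feature matrix:

```python
from tabfhir import ExportConfig, pivot_records, select_records
from tabfhir.store import open_store

store = open_store("store.db")
records = select_records(store, ExportConfig(tables=("condition",)))
matrix = pivot_records(records, aggregation="presence")  # subjects x diagnoses, 0/1
matrix.to_csv("diagnoses_wide.csv")
```

Single stages (`tabfhir query|map|validate|load|export`) persist their
artifacts under a work directory and compose to the same counters as a full
run; `--lenient` downgrades unknown-element failures to warnings.

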