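# Methods

## The harmonization model

`tabfhir` treats harmonization as a five-stage extract-transform-load run
over a directory of CSV tables shaped like an intensive-care EHR export:
query, map, validate, load, export. The stages are deliberately asymmetric
in what they are allowed to do with bad data:

- **query** and **map** fail only on *contract* violations (missing files,
  missing columns, duplicate primary keys, null identity fields). A row
  whose identity cannot be established cannot be harmonized at all.
- **validate** treats bad *values* as data, not exceptions: every mapped
  resource gets a report enumerating all of its issues, failing resources
  are rejected and logged, and the run continues. This is where malformed
  dates surface — timestamp columns are read leniently as text and only
  rendered to FHIR `dateTime` at mapping time, so a value like
  `2023-13-40 00:00:00` flows through to validation and is rejected there
  with `bad_value_format`, feeding a log-and-improve loop rather than
  killing the batch. Integer and decimal columns, by contrast, are parsed
  strictly at read time (nullable failures degrade to null with a warning;
  non-nullable failures abort), because identity and join keys must exist.

## Source schemas and joins

Sixteen table schemas ship by default: twelve core/event tables and four
reference dictionaries. The dictionary pairings are: `chartevents`,
`procedureevents`, `inputevents`, `outputevents` → `d_items` (join on
`itemid`); `labevents` → `d_labitems` (`itemid`); `procedures_icd` →
`d_icd_procedures` and `diagnoses_icd` → `d_icd_diagnoses` (both on the
`(icd_code, icd_version)` pair — ICD-9 and ICD-10 code strings can collide,
so the version is part of the key). Joins are *left* joins: an event
without a dictionary entry keeps null descriptive columns and is logged;
dropping it would silently lose a clinical record. Schemas carry only the
columns the default mapping registry consumes plus primary keys; columns
present in an input file but absent from the registry are excluded from
resources and logged once per run.

## Mapping

The registry (a packaged, user-overridable YAML file) declares per table:
the target R4 core resource type, the ordered id-key columns, fixed
constants for elements R4 requires but the source does not carry
(`Observation.status = "final"`, `Encounter.class = IMP`,
`MedicationRequest.intent = "order"`, ...), the column → dotted-element-path
rules with optional transforms (`to_datetime`, `to_string`, `to_decimal`,
`to_gender_code`, `to_reference:Type`), and a coding-system stamp.

Design choices worth stating:

- **Element paths contain no indices.** Segments that repeat in R4
  (`coding`, `category`, `type`, `dosageInstruction`, ...) are materialized
  as single-element arrays by the path engine, so rule authors write
  `code.coding.display` and never touch FHIRPath.
- **Ids are minted deterministically** as
  `table-key1-key2-...` (sanitized to the FHIR id charset, SHA-1-collapsed
  beyond 64 characters). Deterministic ids are what make re-runs idempotent
  and references resolvable: `Condition.subject` is
  `Patient/<id minted from the same subject_id>`, so referential closure
  holds whenever the referenced core table is in the same run. References
  to `Encounter` reuse the `admissions` recipe (keyed by `hadm_id`).
- **One row, one resource.** Repeated measurements are not merged; the
  document store's upsert provides the only deduplication, keyed by logical
  id.
- **ICD version** is carried both in `Coding.version` (as a string) and in
  a version-specific `Coding.system` URI (`.../icd-9-cm`, `.../icd-10-cm`
  for diagnoses; the CMS ICD-10-PCS URI for procedures). Item-dictionary
  codes get a configurable local system URI, since `itemid`s are
  hospital-local vocabulary.
- Null source values produce no element; a title that is missing after a
  failed dictionary join simply elides `display`/`text` while the code
  survives.

## Validation

Profiles are hand-derived from the R4 core definitions for exactly the
seven resource types the registry emits; full-R4 coverage is a non-goal.
Each profile is an element tree with kind (string, code, integer, decimal,
boolean, dateTime, date, uri, complex), required flag, repetition flag,
value-set bindings for status-like codes, and choice groups (`value[x]`,
`effective[x]`, `performed[x]`, `medication[x]`) enforcing at-most-one
(and, where R4 demands, at-least-one) alternative. `dateTime` values must
match the R4 lexical form *including a zone offset when a time is present*
and must be real calendar dates (February 30 fails even though it matches
the regex shape). Unknown elements fail in strict mode (default) and only
warn in lenient mode — the flag exists because reasonable validators
disagree on leniency. All issues for a resource are collected rather than
failing fast, so one log line explains everything wrong with a record.

The test suite cross-checks pass/fail against a second, independently
written minimal structural checker on the full generated corpus and on
systematically mutated variants (every required element deleted once).

## Patient-model store

One JSON document per resource, grouped by type, keyed by
`(resource_type, id)`. Writes are upserts: an identical document is a
no-op, a changed one replaces the old with a logged notice — harmonizing
the same local data twice must not duplicate it. Insertion order is
preserved and drives export order, so exports are deterministic. Two
backends share the contract: an embedded SQLite file (default) and a
directory layout `store/<Type>/<id>.json` for manual inspection; a server
RDBMS would slot in behind the same interface but is out of scope.

## Flat export and pivot

Extraction rules per resource type name prioritized dotted paths for the
feature name, the value, and each metadata label. The feature name prefers
`code.text` (stable across coding systems) and falls back to
`coding.display`, then `coding.code` — the fallback matters precisely when
a dictionary entry was missing upstream. Value choices: `Observation` →
quantity value (unit in metadata) or string value; `Condition`/`Procedure`
→ the coding's code; medication types → medication code or text;
`Encounter` → class code. `Patient` resources carry identity only and are
not flattened. Default metadata labels: `resource_id`, `subject_ref`,
`encounter_ref`, `effective_time`, `coding_system`, `coding_version`,
`unit`; an export config can whitelist-trim them and filter by table and
feature name. Multi-component observations yield one record per component
in addition to the root record. Every exported object has exactly the four
keys; a JSON Schema for the record ships with the package and a structural
checker enforces it in tests.

The pivot is the two-step "tensorization": normalize records to a long
(subject, encounter, feature, value) table — records without a subject
reference are skipped with a warning — then reshape wide with one of three
aggregations: `presence` (0/1; the encoding for coded diagnoses), `mean`,
or `last` by insertion order. Missing numeric cells stay explicitly missing
(NaN), never silent zeros; only the presence pivot uses 0. Column order is
lexicographic and row order sorted, for byte-stable CSV output.

## Synthetic cohorts

The generator emits all sixteen tables with referentially consistent keys:
every event's `hadm_id` exists in `admissions`, every ICD code in its
dictionary, timestamps strictly ordered admit < event < discharge within a
fixed synthetic year (2021). Defaults are a 100-patient cohort with 1–3
admissions per patient and a handful of events of each kind per admission
(1–5 diagnoses, 2–8 lab events, ...) — enough structure to exercise every
join, mapping rule and reference without pretending to be epidemiology.
Value realism is schematic: ~45 ICD codes, 12 ICD procedure codes, 20 lab
items and ~28 chart/procedure/input/output items from small bundled
dictionaries; vitals and lab values are uniform draws in plausible ranges.
Passing tests therefore demonstrate structural and contract correctness —
schema conformance, join/key integrity, conservation, determinism — not
clinical plausibility or distributional fidelity to any real hospital.

Each table draws from its own seed-addressable substream
(`default_rng([seed, table_index])`), so the same spec and seed give
byte-identical CSVs and adding one table never perturbs another.

Defect injection reproduces the three failure modes the pipeline must
handle, at configurable per-row rates and reproducibly under seed:

- `bad_date` — a timestamp cell becomes a malformed calendar date (with a
  unique suffix so composite keys stay distinct); the mapped resource is
  rejected at validation.
- `null_required` — nulls the administration window of an `inputevents`
  row. This is the one column set in the emitted element set that feeds a
  *required* R4 element (`MedicationAdministration.effective[x]`) while not
  being a primary key — nulling a key column would abort at mapping (an
  identity error) rather than reject at validation, which is a different
  failure class.
- `missing_dictionary` — removes used `d_icd_diagnoses` rows; downstream
  this yields null titles after the join (logged), a Condition that still
  validates, and a flat record that falls back to the code as its feature
  name. No rejection, by design.

The injection manifest records every mutation, and each `bad_date` /
`null_required` entry accounts for exactly one rejected resource — the
invariant the defect-accounting tests and the acceptance script assert.

## Problem sizes and numerical choices

The test suite runs on a 6-patient cohort (~300 rows, ~300 resources) for
unit and property tests and a 100-patient cohort (~5,000 resources) for the
acceptance checks; the acceptance script uses the 100-patient default.
Property tests (id uniqueness, pivot-vs-groupby agreement) use derandomized
hypothesis search. There is no floating-point estimation anywhere in the
pipeline; the only numeric care points are CSV round-tripping of decimals
(written via `repr` for shortest exact form) and mean aggregation in the
pivot, which is plain pandas arithmetic checked against a brute-force
groupby oracle.

## Known limitations

- Only the seven emitted R4 core resource types have profiles; no
  extensions, profiles (in the FHIR sense), or other FHIR releases.
- No terminology/semantic validation: codes are carried, not checked for
  membership in ICD or LOINC, and references are checked for closure within
  a run, not resolved against a server.
- Element-level mappings beyond the diagnosis table are this package's own
  documented defaults, confined to R4 core elements and overridable via the
  registry file.
- The query stage reads files; live database connectivity, scheduling and
  deployment concerns (communication servers, network security, federated
  learning) are out of scope.
- Timestamps are treated as naive local times and rendered with a single
  configurable zone offset (default UTC); per-source timezone handling is
  not modeled.
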