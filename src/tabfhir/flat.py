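"""Flat 4-key export and the long→wide pivot to a feature matrix.

The export stage turns each stored FHIR resource into flat records with
exactly four keys — ``feature_name``, ``table_name``, ``value`` and
``metadata`` — so downstream tooling can select and filter without any
knowledge of FHIRPath or the nested resource hierarchy.  The feature
name comes from the code's ``text`` element: unlike ``display``, which
can change with the coding system, the text stays stable and therefore
identifies the feature.  ``table_name`` is the lowercased resource type
and ``metadata`` carries dates, references, coding-system details and
the resource id.

Selection is driven by a small configuration (tables and features of
interest); the pivot step then normalizes records to a long
(subject, encounter, feature, value) table and reshapes it wide —
binary presence for coded diagnoses, mean or last-by-insertion-order for
numeric values — giving the matrix form ("tensor") that mainstream
ML frameworks consume.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from numbers import Number
from pathlib import Path
from typing import Any, Iterable, Optional, Sequence

import pandas as pd
import yaml

from .errors import ConfigurationError, ExportError
from .mapping import FhirResource
from .paths import get_path, resolve_first
from .store import BaseStore

logger = logging.getLogger("tabfhir.flat")

FLAT_KEYS = ("feature_name", "table_name", "value", "metadata")

#: Metadata labels shipped by default (whitelist-trimmable).
DEFAULT_METADATA_LABELS = (
    "resource_id", "subject_ref", "encounter_ref", "effective_time",
    "coding_system", "coding_version", "unit",
)


@dataclass(frozen=True)
class FlatRecord:
    feature_name: str
    table_name: str
    value: Any
    metadata: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "feature_name": self.feature_name,
            "table_name": self.table_name,
            "value": self.value,
            "metadata": dict(self.metadata),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FlatRecord":
        extra = set(d) - set(FLAT_KEYS)
        missing = set(FLAT_KEYS) - set(d)
        if extra or missing:
            raise ExportError(f"record keys wrong: extra={sorted(extra)} missing={sorted(missing)}")
        return cls(d["feature_name"], d["table_name"], d["value"], dict(d["metadata"]))


@dataclass(frozen=True)
class ExtractionRule:
    """How one resource type flattens: where to read name, value, metadata.

    Paths are prioritized lists; the first that resolves wins.  The
    feature name must resolve (export error otherwise); a value that
    resolves nowhere yields a null-valued record, logged.
    """

    resource_type: str
    feature_name_paths: tuple[str, ...]
    value_paths: tuple[str, ...]
    metadata_paths: tuple[tuple[str, tuple[str, ...]], ...] = ()
    component_element: Optional[str] = None  # e.g. "component" for Observation

    def metadata_map(self) -> dict[str, tuple[str, ...]]:
        return dict(self.metadata_paths)


def _mp(**labels: Sequence[str] | str) -> tuple[tuple[str, tuple[str, ...]], ...]:
    out = []
    for label, paths in labels.items():
        if isinstance(paths, str):
            paths = (paths,)
        out.append((label, tuple(paths)))
    return tuple(out)


def default_extraction_rules() -> dict[str, ExtractionRule]:
    """Shipped flattening rules for the emitted resource types.

    Patient resources carry identity only, no measurement, and are not
    flattened.  Value choices: Observation → quantity value (unit in
    metadata) or string value; Condition/Procedure → the coding's code
    (ICD or item id), with the human-readable title as feature name;
    medication resources → the medication code or text; Encounter → the
    class code.
    """
    rules = [
        ExtractionRule(
            "Observation",
            feature_name_paths=("code.text", "code.coding.display", "code.coding.code"),
            value_paths=("valueQuantity.value", "valueString"),
            metadata_paths=_mp(
                resource_id="id",
                subject_ref="subject.reference",
                encounter_ref="encounter.reference",
                effective_time="effectiveDateTime",
                coding_system="code.coding.system",
                coding_version="code.coding.version",
                unit="valueQuantity.unit",
            ),
            component_element="component",
        ),
        ExtractionRule(
            "Condition",
            feature_name_paths=("code.text", "code.coding.display", "code.coding.code"),
            value_paths=("code.coding.code",),
            metadata_paths=_mp(
                resource_id="id",
                subject_ref="subject.reference",
                encounter_ref="encounter.reference",
                coding_system="code.coding.system",
                coding_version="code.coding.version",
            ),
        ),
        ExtractionRule(
            "Procedure",
            feature_name_paths=("code.text", "code.coding.display", "code.coding.code"),
            value_paths=("code.coding.code",),
            metadata_paths=_mp(
                resource_id="id",
                subject_ref="subject.reference",
                encounter_ref="encounter.reference",
                effective_time=("performedDateTime", "performedPeriod.start"),
                coding_system="code.coding.system",
                coding_version="code.coding.version",
            ),
        ),
        ExtractionRule(
            "MedicationRequest",
            feature_name_paths=("medicationCodeableConcept.text",
                                "medicationCodeableConcept.coding.display"),
            value_paths=("medicationCodeableConcept.coding.code",
                         "medicationCodeableConcept.text"),
            metadata_paths=_mp(
                resource_id="id",
                subject_ref="subject.reference",
                encounter_ref="encounter.reference",
                effective_time="authoredOn",
                unit="dispenseRequest.quantity.unit",
            ),
        ),
        ExtractionRule(
            "MedicationAdministration",
            feature_name_paths=("medicationCodeableConcept.text",
                                "medicationCodeableConcept.coding.display",
                                "medicationCodeableConcept.coding.code"),
            value_paths=("medicationCodeableConcept.coding.code",
                         "medicationCodeableConcept.text"),
            metadata_paths=_mp(
                resource_id="id",
                subject_ref="subject.reference",
                encounter_ref="context.reference",
                effective_time="effectivePeriod.start",
                coding_system="medicationCodeableConcept.coding.system",
                unit="dosage.dose.unit",
            ),
        ),
        ExtractionRule(
            "Encounter",
            feature_name_paths=("type.text", "class.code"),
            value_paths=("class.code", "status"),
            metadata_paths=_mp(
                resource_id="id",
                subject_ref="subject.reference",
                effective_time="period.start",
            ),
        ),
    ]
    return {r.resource_type: r for r in rules}


def load_extraction_rules(path: str | Path) -> dict[str, ExtractionRule]:
    """User-supplied extraction rules (YAML/JSON), same shape as defaults."""
    with open(path, "rt", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    rules = {}
    for rtype, block in doc.items():
        meta = block.get("metadata_paths", {})
        rules[rtype] = ExtractionRule(
            resource_type=rtype,
            feature_name_paths=tuple(block["feature_name_paths"]),
            value_paths=tuple(block["value_paths"]),
            metadata_paths=tuple(
                (label, tuple([p] if isinstance(p, str) else p)) for label, p in meta.items()
            ),
            component_element=block.get("component_element"),
        )
    return rules


@dataclass(frozen=True)
class ExportConfig:
    """Tables/features of interest; empty selectors mean select-all."""

    tables: tuple[str, ...] = ()
    features: tuple[str, ...] = ()
    metadata_labels: tuple[str, ...] = ()

    @classmethod
    def from_file(cls, path: str | Path) -> "ExportConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(
            tables=tuple(doc.get("tables", ())),
            features=tuple(doc.get("features", ())),
            metadata_labels=tuple(doc.get("metadata_labels", ())),
        )


def _scalarize(v: Any) -> Any:
    if isinstance(v, float) and v.is_integer():
        return v  # keep numeric type; JSON renders 114.0 -> 114.0; leave as float
    return v


def flatten_resource(resource: FhirResource, rule: ExtractionRule) -> list[FlatRecord]:
    """One FlatRecord per logical observation carried by the resource.

    The root value yields one record; a multi-component resource (e.g. a
    blood-pressure panel) yields one further record per component, named
    by the component code's text.
    """
    if rule.resource_type != resource.resource_type:
        raise ExportError(
            f"rule for {rule.resource_type} applied to {resource.resource_type}"
        )
    body = resource.body
    feature = resolve_first(body, rule.feature_name_paths)
    if feature is None:
        raise ExportError(
            f"feature name unresolvable for resource {resource.resource_type}/{resource.id}"
        )
    table_name = resource.resource_type.lower()
    metadata: dict[str, Any] = {}
    for label, paths in rule.metadata_paths:
        v = resolve_first(body, paths)
        if v is not None:
            metadata[label] = _scalarize(v)
    metadata.setdefault("resource_id", resource.id)
    value = resolve_first(body, rule.value_paths)
    if value is None:
        logger.warning(
            "resource %s/%s: no value path resolved; exporting null value",
            resource.resource_type, resource.id,
        )
    records = [FlatRecord(str(feature), table_name, _scalarize(value), metadata)]
    if rule.component_element and isinstance(body.get(rule.component_element), list):
        for comp in body[rule.component_element]:
            cf = resolve_first(comp, ("code.text", "code.coding.display", "code.coding.code"))
            if cf is None:
                raise ExportError(
                    f"component feature name unresolvable in {resource.resource_type}/{resource.id}"
                )
            cv = resolve_first(comp, ("valueQuantity.value", "valueString"))
            cmeta = dict(metadata)
            cunit = get_path(comp, "valueQuantity.unit")
            if cunit is not None:
                cmeta["unit"] = cunit
            elif "unit" in cmeta:
                del cmeta["unit"]
            records.append(FlatRecord(str(cf), table_name, _scalarize(cv), cmeta))
    return records


def select_records(
    store: BaseStore,
    config: Optional[ExportConfig] = None,
    rules: Optional[dict[str, ExtractionRule]] = None,
) -> list[FlatRecord]:
    """Flatten stored resources per config, in store insertion order."""
    config = config or ExportConfig()
    rules = rules if rules is not None else default_extraction_rules()
    known_tables = {r.resource_type.lower() for r in rules.values()}
    for t in config.tables:
        if t not in known_tables:
            logger.warning("export config selects unknown table %r; contributes nothing", t)
    out: list[FlatRecord] = []
    for resource in store.iter_all():
        table_name = resource.resource_type.lower()
        if config.tables and table_name not in config.tables:
            continue
        rule = rules.get(resource.resource_type)
        if rule is None:
            continue  # type not flattenable (e.g. Patient)
        for rec in flatten_resource(resource, rule):
            if config.features and rec.feature_name not in config.features:
                continue
            if config.metadata_labels:
                rec = FlatRecord(
                    rec.feature_name, rec.table_name, rec.value,
                    {k: v for k, v in rec.metadata.items() if k in config.metadata_labels},
                )
            out.append(rec)
    return out


# ---------------------------------------------------------------------------
# Serialization + record-shape checking
# ---------------------------------------------------------------------------

def flat_record_schema() -> dict:
    """The shipped JSON Schema document for the 4-key record."""
    text = (
        importlib_resources.files("tabfhir.data")
        .joinpath("flat_record.schema.json")
        .read_text(encoding="utf-8")
    )
    return json.loads(text)


def check_flat_dict(d: dict) -> list[str]:
    """Structural check of one exported object against the 4-key contract.

    Returns a list of problems (empty when conformant).
    """
    problems = []
    if set(d) != set(FLAT_KEYS):
        problems.append(f"keys {sorted(d)} != {sorted(FLAT_KEYS)}")
        return problems
    if not isinstance(d["feature_name"], str) or not d["feature_name"]:
        problems.append("feature_name must be a non-empty string")
    if not isinstance(d["table_name"], str) or not d["table_name"].islower():
        problems.append("table_name must be a lowercase resource-type label")
    if d["value"] is not None and not isinstance(d["value"], (str, Number, bool)):
        problems.append("value must be primitive or null")
    if not isinstance(d["metadata"], dict):
        problems.append("metadata must be an object")
    else:
        for k, v in d["metadata"].items():
            if v is not None and not isinstance(v, (str, Number, bool)):
                problems.append(f"metadata[{k!r}] must be primitive")
    return problems


def export_json(records: Sequence[FlatRecord], path: str | Path, ndjson: bool = False) -> Path:
    """Write records as a JSON array (default) or NDJSON (one per line)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dicts = [r.to_dict() for r in records]
    try:
        with open(path, "wt", encoding="utf-8") as fh:
            if ndjson:
                for d in dicts:
                    fh.write(json.dumps(d, ensure_ascii=False) + "\n")
            else:
                json.dump(dicts, fh, ensure_ascii=False, indent=2)
    except OSError as exc:
        raise ExportError(f"cannot write {path}: {exc}")
    return path


def read_flat_json(path: str | Path, ndjson: bool = False) -> list[FlatRecord]:
    path = Path(path)
    with open(path, "rt", encoding="utf-8") as fh:
        if ndjson:
            dicts = [json.loads(line) for line in fh if line.strip()]
        else:
            dicts = json.load(fh)
    return [FlatRecord.from_dict(d) for d in dicts]


# ---------------------------------------------------------------------------
# Pivot to a feature matrix
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Wide subject(/encounter) × feature matrix.

    Missing cells are explicit (NaN/empty) for numeric aggregations and 0
    only under the binary presence pivot; columns are ordered
    lexicographically for determinism.
    """

    frame: pd.DataFrame
    index_policy: str
    aggregation: str

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    @property
    def feature_names(self) -> list[str]:
        return list(self.frame.columns)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.frame.to_csv(path, lineterminator="\n")
        return path


def pivot_records(
    records: Sequence[FlatRecord],
    index_policy: str = "subject",
    aggregation: str = "presence",
) -> FeatureTable:
    """Two-step tensorization: long normalization, then the wide pivot.

    Step 1 normalizes records into a long table (subject, encounter,
    feature_name, value); records without a subject reference are skipped
    with a warning.  Step 2 reshapes wide with the chosen aggregation:

    - ``presence``: 1 where the (index, feature) pair occurs, else 0 —
      the natural encoding for coded diagnoses;
    - ``mean``: arithmetic mean of numeric values over duplicates;
    - ``last``: last value in insertion order.
    """
    if index_policy not in ("subject", "subject_encounter"):
        raise ConfigurationError(f"unknown index policy {index_policy!r}")
    if aggregation not in ("presence", "mean", "last"):
        raise ConfigurationError(f"unknown aggregation {aggregation!r}")
    rows = []
    for order, rec in enumerate(records):
        subject = rec.metadata.get("subject_ref")
        if subject is None:
            logger.warning("record %r lacks a subject reference; skipped", rec.feature_name)
            continue
        rows.append(
            {
                "subject": subject,
                "encounter": rec.metadata.get("encounter_ref"),
                "feature_name": rec.feature_name,
                "value": rec.value,
                "_order": order,
            }
        )
    idx_cols = ["subject"] if index_policy == "subject" else ["subject", "encounter"]
    if not rows:
        empty = pd.DataFrame()
        empty.index.name = "subject"
        return FeatureTable(empty, index_policy, aggregation)
    long = pd.DataFrame(rows)
    if aggregation == "presence":
        long["_one"] = 1
        wide = long.pivot_table(
            index=idx_cols, columns="feature_name", values="_one",
            aggfunc="max", fill_value=0,
        )
    elif aggregation == "mean":
        long["value"] = pd.to_numeric(long["value"], errors="coerce")
        wide = long.pivot_table(
            index=idx_cols, columns="feature_name", values="value", aggfunc="mean"
        )
    else:  # last by insertion order
        long = long.sort_values("_order").drop_duplicates(
            subset=idx_cols + ["feature_name"], keep="last"
        )
        wide = long.pivot(index=idx_cols, columns="feature_name", values="value")
    wide = wide.sort_index(axis=0).sort_index(axis=1)
    wide.columns = [str(c) for c in wide.columns]
    return FeatureTable(wide, index_policy, aggregation)
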