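"""Declarative mapping of joined source rows to FHIR R4 core resources.

The registry is the machine form of a table→resource assignment plus
per-column element rules.  Twelve hospital tables map onto seven R4 core
resource types: patients→Patient, admissions/transfers→Encounter,
chart/lab/microbiology/output events→Observation, procedure events and
ICD-coded procedures→Procedure, prescriptions→MedicationRequest,
input events→MedicationAdministration and ICD-coded diagnoses→Condition.
Columns without a matching R4-core concept are excluded from the
resource (and logged once per run); null source values produce no
element.  One source row yields exactly one resource.

Ids are minted deterministically from primary-key values so re-runs are
idempotent and references (``Patient/...``, ``Encounter/...``) resolve
to resources minted in the same run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from datetime import datetime
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Any, Iterable, Optional

import yaml

from .errors import (
    ConfigurationError,
    IdentityError,
    UnknownTableError,
    UnknownVocabularyError,
)
from .paths import get_path, set_path
from .schemas import SourceTable

logger = logging.getLogger("tabfhir.mapping")

# Canonical FHIR system URIs for the vocabularies the registry can stamp.
# ICD version is additionally carried in Coding.version.
CODING_SYSTEMS: dict[str, dict[str, str]] = {
    "icd_diagnoses": {
        "9": "http://hl7.org/fhir/sid/icd-9-cm",
        "10": "http://hl7.org/fhir/sid/icd-10-cm",
    },
    "icd_procedures": {
        "9": "http://hl7.org/fhir/sid/icd-9-cm",
        "10": "http://www.cms.gov/Medicare/Coding/ICD10",
    },
}

_ID_SAFE = re.compile(r"[^A-Za-z0-9.-]+")
_ID_MAX = 64


def coding_system_uri(code_kind: str, version: Any = None, *, local_system_uri: str | None = None) -> str:
    """System URI for a vocabulary; ``local_items`` uses a configurable URI."""
    if code_kind == "local_items":
        return local_system_uri or DEFAULT_LOCAL_SYSTEM_URI
    try:
        table = CODING_SYSTEMS[code_kind]
    except KeyError:
        raise UnknownVocabularyError(code_kind)
    key = str(int(version)) if isinstance(version, float) else str(version)
    if key not in table:
        raise UnknownVocabularyError(f"{code_kind} version {version!r}")
    return table[key]


def make_resource_id(table_name: str, key_values: Iterable[Any]) -> str:
    """Deterministic, URL-safe resource id: ``table-key1-key2-...``.

    Values are sanitized to the FHIR id charset; ids longer than 64
    characters collapse to ``table-<sha1 digest>`` (still deterministic
    and collision-free per distinct key tuple in practice).
    """
    keys = list(key_values)
    if not keys:
        raise IdentityError(f"{table_name}: empty key tuple")
    parts = [_ID_SAFE.sub(".", table_name.lower())]
    for v in keys:
        if v is None:
            raise IdentityError(f"{table_name}: null key component in {keys!r}")
        if isinstance(v, float) and v.is_integer():
            v = int(v)
        parts.append(_ID_SAFE.sub(".", str(v)))
    rid = "-".join(parts)
    if len(rid) > _ID_MAX:
        digest = hashlib.sha1(rid.encode("utf-8")).hexdigest()
        rid = f"{parts[0]}-{digest}"[:_ID_MAX]
    return rid


@dataclass(frozen=True)
class MappingRule:
    source_table: str
    source_column: str
    element_path: str
    transform: str = "identity"

    def __post_init__(self) -> None:
        if not self.element_path or "[" in self.element_path:
            raise ConfigurationError(
                f"rule {self.source_table}.{self.source_column}: element_path must be a "
                f"plain dotted path without indices, got {self.element_path!r}"
            )


@dataclass(frozen=True)
class CodingSpec:
    vocabulary: str
    system_path: str
    version_column: Optional[str] = None


@dataclass(frozen=True)
class TableMapping:
    resource_type: str
    id_keys: tuple[str, ...]
    rules: tuple[MappingRule, ...]
    constants: tuple[tuple[str, Any], ...] = ()
    coding: Optional[CodingSpec] = None


@dataclass(frozen=True)
class MappingRegistry:
    """table→resource assignments, element rules and id recipes."""

    tables: dict[str, TableMapping]
    reference_targets: dict[str, str]  # resource type -> table whose id recipe backs references
    local_system_uri: str

    @property
    def table_to_resource(self) -> dict[str, str]:
        return {t: m.resource_type for t, m in self.tables.items()}

    def resource_types(self) -> set[str]:
        return set(self.table_to_resource.values())

    def __post_init__(self) -> None:
        known = self.resource_types()
        for t, m in self.tables.items():
            for r in m.rules:
                if r.transform.startswith("to_reference:"):
                    target = r.transform.split(":", 1)[1]
                    if target not in known:
                        raise ConfigurationError(
                            f"{t}.{r.source_column}: reference target {target!r} not in registry"
                        )
                if r.source_table != t:
                    raise ConfigurationError(
                        f"rule table {r.source_table!r} filed under {t!r}"
                    )


DEFAULT_LOCAL_SYSTEM_URI = "http://terminology.example.org/CodeSystem/hospital-items"


def _registry_from_dict(doc: dict) -> MappingRegistry:
    tables: dict[str, TableMapping] = {}
    for name, block in doc["tables"].items():
        rules = tuple(
            MappingRule(
                source_table=name,
                source_column=r["column"],
                element_path=r["path"],
                transform=r.get("transform", "identity"),
            )
            for r in block.get("rules", [])
        )
        coding = None
        if "coding" in block:
            c = block["coding"]
            coding = CodingSpec(
                vocabulary=c["vocabulary"],
                system_path=c["system_path"],
                version_column=c.get("version_column"),
            )
        tables[name] = TableMapping(
            resource_type=block["resource_type"],
            id_keys=tuple(block["id_keys"]),
            rules=rules,
            constants=tuple(sorted((block.get("constants") or {}).items())),
            coding=coding,
        )
    return MappingRegistry(
        tables=tables,
        reference_targets=dict(doc.get("reference_targets", {})),
        local_system_uri=doc.get("local_system_uri", DEFAULT_LOCAL_SYSTEM_URI),
    )


def load_registry(path: str | Path) -> MappingRegistry:
    """Load a user-supplied registry file (YAML or JSON)."""
    with open(path, "rt", encoding="utf-8") as fh:
        return _registry_from_dict(yaml.safe_load(fh))


def default_registry() -> MappingRegistry:
    """The shipped registry (packaged data file)."""
    text = (
        importlib_resources.files("tabfhir.data")
        .joinpath("default_registry.yaml")
        .read_text(encoding="utf-8")
    )
    return _registry_from_dict(yaml.safe_load(text))


def resource_type_for(registry: MappingRegistry, table_name: str) -> str:
    try:
        return registry.tables[table_name].resource_type
    except KeyError:
        raise UnknownTableError(table_name)


@dataclass
class FhirResource:
    """A single FHIR R4 core resource as a nested JSON document."""

    resource_type: str
    id: str
    body: dict

    def to_json(self, indent: Optional[int] = None) -> str:
        return json.dumps(self.body, indent=indent, ensure_ascii=False)

    @classmethod
    def from_body(cls, body: dict) -> "FhirResource":
        return cls(resource_type=body.get("resourceType", ""), id=body.get("id", ""), body=body)


# ---------------------------------------------------------------------------
# Value transforms
# ---------------------------------------------------------------------------

_GENDER = {"M": "male", "F": "female", "m": "male", "f": "female"}


class Mapper:
    """Stateful mapping engine (tracks once-per-run unmapped-column logs).

    ``zone_offset`` is appended to naive source timestamps when rendering
    FHIR dateTime values (default UTC).  A timestamp that fails to parse
    is passed through verbatim so that syntactic validation can reject
    the resource and log the defect instead of aborting the batch.
    """

    def __init__(self, registry: Optional[MappingRegistry] = None, zone_offset: str = "+00:00"):
        self.registry = registry or default_registry()
        self.zone_offset = zone_offset
        self._unmapped_logged: set[tuple[str, str]] = set()

    # -- transforms -------------------------------------------------------
    def _to_datetime(self, value: Any) -> Any:
        if isinstance(value, datetime):
            return value.isoformat() + self.zone_offset
        text = str(value)
        try:
            dt = datetime.fromisoformat(text)
        except ValueError:
            logger.warning("unparseable timestamp %r passed through for validation", text)
            return text
        if dt.tzinfo is not None:
            return dt.isoformat()
        return dt.isoformat() + self.zone_offset

    def transform_value(self, transform: str, value: Any, table_name: str) -> Any:
        if transform == "identity":
            return value
        if transform == "to_string":
            if isinstance(value, float) and value.is_integer():
                return str(int(value))
            return str(value)
        if transform == "to_integer":
            return int(value)
        if transform == "to_decimal":
            return float(value)
        if transform == "to_datetime":
            return self._to_datetime(value)
        if transform == "to_gender_code":
            return _GENDER.get(str(value), str(value).lower())
        if transform.startswith("to_reference:"):
            return self.make_reference(transform.split(":", 1)[1], value)
        raise ConfigurationError(f"unknown transform {transform!r} for table {table_name}")

    def make_reference(self, target_type: str, raw_id: Any) -> dict:
        """Literal reference ``{"reference": "Type/<minted id>"}``.

        The minted id reuses the id recipe of the table that produces the
        target type, so e.g. a Condition's subject resolves to the
        Patient minted from the same subject_id.
        """
        if raw_id is None:
            raise IdentityError(f"null id for reference to {target_type}")
        source_table = self.registry.reference_targets.get(target_type)
        if source_table is None:
            raise ConfigurationError(f"no reference recipe for resource type {target_type!r}")
        return {"reference": f"{target_type}/{make_resource_id(source_table, [raw_id])}"}

    # -- core -------------------------------------------------------------
    def map_row(self, table_name: str, row: dict) -> FhirResource:
        """Map one joined source row to a single FHIR resource."""
        try:
            tm = self.registry.tables[table_name]
        except KeyError:
            raise UnknownTableError(table_name)
        key_values = []
        for k in tm.id_keys:
            v = row.get(k)
            if v is None:
                raise IdentityError(f"{table_name}: missing primary-key value {k!r}")
            key_values.append(v)
        rid = make_resource_id(table_name, key_values)
        body: dict = {"resourceType": tm.resource_type, "id": rid}
        for path, value in tm.constants:
            set_path(body, path, value)
        ruled_columns = {r.source_column for r in tm.rules}
        for rule in tm.rules:
            value = row.get(rule.source_column)
            if value is None:
                continue
            set_path(body, rule.element_path, self.transform_value(rule.transform, value, table_name))
        if tm.coding is not None:
            ruled_columns.add(tm.coding.version_column or "")
            code_root = tm.coding.system_path.rsplit(".", 1)[0]
            if get_path(body, code_root + ".code") is not None:
                version = row.get(tm.coding.version_column) if tm.coding.version_column else None
                if tm.coding.version_column is None or version is not None:
                    uri = coding_system_uri(
                        tm.coding.vocabulary, version, local_system_uri=self.registry.local_system_uri
                    )
                    set_path(body, tm.coding.system_path, uri)
        for col, value in row.items():
            if col in ruled_columns or col in tm.id_keys:
                continue
            key = (table_name, col)
            if key not in self._unmapped_logged:
                self._unmapped_logged.add(key)
                logger.warning(
                    "table %s: column %s has no matching FHIR concept; excluded from resources",
                    table_name, col,
                )
        return FhirResource(resource_type=tm.resource_type, id=rid, body=body)

    def map_table(self, table: SourceTable) -> list[FhirResource]:
        """Map every row of a table, preserving input order."""
        out: list[FhirResource] = []
        for i, row in enumerate(table.rows()):
            try:
                out.append(self.map_row(table.schema.table_name, row))
            except IdentityError as exc:
                raise IdentityError(f"row {i}: {exc}") from exc
        return out


def make_reference(target_type: str, raw_id: Any, registry: Optional[MappingRegistry] = None) -> dict:
    """Module-level convenience over :meth:`Mapper.make_reference`."""
    return Mapper(registry).make_reference(target_type, raw_id)


def write_ndjson(resources: Iterable[FhirResource], path: str | Path) -> None:
    """Bulk serialization: one resource JSON document per line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wt", encoding="utf-8") as fh:
        for r in resources:
            fh.write(json.dumps(r.body, ensure_ascii=False) + "\n")


def read_ndjson(path: str | Path) -> list[FhirResource]:
    out = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(FhirResource.from_body(json.loads(line)))
    return out
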