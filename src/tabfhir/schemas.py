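"""Source-table schemas: reading, joining and batching hospital tables.

This is the pipeline's query stage.  At desk scale the hospital database
is represented by a directory of CSV files, one per table, mirroring the
layout of an intensive-care EHR dataset: *core* tables (patients,
admissions, transfers), *event* tables (chart, lab, procedure, input,
output, microbiology events, prescriptions, ICD-coded procedures and
diagnoses) and *reference dictionaries* (d_items, d_labitems,
d_icd_procedures, d_icd_diagnoses) that translate item ids and ICD codes
into human-readable labels.  Event tables are merged with their
dictionary before mapping so each record carries a complete description.

Schemas cover only the columns the default mapping registry consumes,
plus primary keys.

Notes on value kinds: ``integer`` and ``decimal`` columns are parsed
strictly (a non-nullable cell that fails to parse aborts the read);
``timestamp`` columns are kept lexically as text and parsed only when a
mapping rule renders them into a FHIR dateTime — a malformed date
therefore flows through to syntactic validation, which rejects the
resource and logs the error rather than killing the batch.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

from .errors import (
    ConfigurationError,
    ParseError,
    SchemaError,
    TableIntegrityError,
    UnknownTableError,
)

logger = logging.getLogger("tabfhir.source")

VALUE_KINDS = ("integer", "decimal", "text", "timestamp")


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    kind: str  # one of VALUE_KINDS
    nullable: bool = False

    def __post_init__(self) -> None:
        if self.kind not in VALUE_KINDS:
            raise SchemaError(f"unknown value kind {self.kind!r} for column {self.name!r}")


@dataclass(frozen=True)
class ReferenceJoin:
    """Pairing of an event table with its reference dictionary."""

    reference_table: str
    join_key: tuple[str, ...]


@dataclass(frozen=True)
class TableSchema:
    table_name: str
    columns: tuple[ColumnSpec, ...]
    primary_key: tuple[str, ...]
    reference_join: Optional[ReferenceJoin] = None

    def __post_init__(self) -> None:
        names = [c.name for c in self.columns]
        if len(set(names)) != len(names):
            raise SchemaError(f"{self.table_name}: duplicate column names")
        by_name = {c.name: c for c in self.columns}
        for pk in self.primary_key:
            col = by_name.get(pk)
            if col is None:
                raise SchemaError(f"{self.table_name}: primary key column {pk!r} not in columns")
            if col.nullable:
                raise SchemaError(f"{self.table_name}: primary key column {pk!r} must be non-nullable")

    @property
    def column_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.columns)

    def column(self, name: str) -> ColumnSpec:
        for c in self.columns:
            if c.name == name:
                return c
        raise SchemaError(f"{self.table_name}: no column {name!r}")

    def to_dict(self) -> dict:
        d = {
            "table_name": self.table_name,
            "columns": [
                {"name": c.name, "kind": c.kind, "nullable": c.nullable} for c in self.columns
            ],
            "primary_key": list(self.primary_key),
        }
        if self.reference_join:
            d["reference_join"] = {
                "reference_table": self.reference_join.reference_table,
                "join_key": list(self.reference_join.join_key),
            }
        return d


_PANDAS_DTYPES = {"integer": "Int64", "decimal": "float64", "text": "object", "timestamp": "object"}


class SourceTable:
    """A typed tabular dataset backed by a pandas DataFrame.

    Construction enforces the schema invariants: exact column set (in
    schema order), per-kind typing, non-nullability and primary-key
    uniqueness.
    """

    def __init__(self, schema: TableSchema, frame: pd.DataFrame):
        missing = [c for c in schema.column_names if c not in frame.columns]
        if missing:
            raise SchemaError(f"{schema.table_name}: missing columns {missing}")
        extra = [c for c in frame.columns if c not in schema.column_names]
        if extra:
            raise SchemaError(f"{schema.table_name}: unexpected columns {extra}")
        frame = frame[list(schema.column_names)].reset_index(drop=True)
        for col in schema.columns:
            series = frame[col.name]
            if not col.nullable and series.isna().any():
                idx = int(series.isna().idxmax())
                raise ParseError(
                    f"{schema.table_name}: null in non-nullable column {col.name!r} at row {idx}"
                )
        if schema.primary_key:
            dup = frame.duplicated(subset=list(schema.primary_key))
            if dup.any():
                idx = int(dup.idxmax())
                raise TableIntegrityError(
                    f"{schema.table_name}: duplicate primary key at row {idx}"
                )
        self.schema = schema
        self.frame = frame

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    def rows(self) -> Iterator[dict]:
        """Yield rows as plain dicts with Python scalars; NA becomes None."""
        for rec in self.frame.itertuples(index=False, name=None):
            row = {}
            for col, val in zip(self.schema.column_names, rec):
                if pd.isna(val):
                    row[col] = None
                elif isinstance(val, float) and val.is_integer() and self.schema.column(col).kind == "integer":
                    row[col] = int(val)
                else:
                    row[col] = val.item() if hasattr(val, "item") else val
            yield row

    def equals(self, other: "SourceTable") -> bool:
        return self.schema == other.schema and self.frame.equals(other.frame)


def _coerce_frame(raw: pd.DataFrame, schema: TableSchema) -> pd.DataFrame:
    """Apply per-column kinds to a string-typed frame read from CSV."""
    out = {}
    for col in schema.columns:
        s = raw[col.name]
        s = s.where(~s.isin([""]), other=pd.NA) if s.dtype == object else s
        if col.kind == "integer":
            parsed = pd.to_numeric(s, errors="coerce").astype("Int64")
            bad = parsed.isna() & s.notna()
        elif col.kind == "decimal":
            parsed = pd.to_numeric(s, errors="coerce").astype("float64")
            bad = parsed.isna() & s.notna()
        else:  # text / timestamp stay lexical
            parsed = s.astype("object")
            bad = pd.Series(False, index=s.index)
        if bad.any():
            idx = int(bad.idxmax())
            if col.nullable:
                logger.warning(
                    "table %s: %d unparseable cell(s) in nullable column %s set to null (first at row %d)",
                    schema.table_name, int(bad.sum()), col.name, idx,
                )
            else:
                raise ParseError(
                    f"{schema.table_name}: unparseable value {s[idx]!r} in non-nullable "
                    f"column {col.name!r} at row {idx}"
                )
        out[col.name] = parsed
    return pd.DataFrame(out)


def read_table(path: str | Path, schema: TableSchema) -> SourceTable:
    """Read one CSV (optionally .gz) into a schema-checked SourceTable."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt", encoding="utf-8", newline="") as fh:
        raw = pd.read_csv(fh, dtype=str, keep_default_na=False, na_values=[""])
    missing = [c for c in schema.column_names if c not in raw.columns]
    if missing:
        raise SchemaError(f"{schema.table_name}: CSV {path.name} lacks required columns {missing}")
    return SourceTable(schema, _coerce_frame(raw[list(schema.column_names)], schema))


def write_table(table: SourceTable, path: str | Path) -> None:
    """Write a SourceTable to CSV (RFC-4180, UTF-8, header row)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = table.frame.copy()
    # render floats compactly so write->read round-trips bit-for-bit
    for col in table.schema.columns:
        if col.kind == "decimal":
            frame[col.name] = frame[col.name].map(
                lambda v: "" if pd.isna(v) else repr(float(v))
            )
    if path.suffix == ".gz":
        with gzip.open(path, "wt", encoding="utf-8", newline="") as fh:
            frame.to_csv(fh, index=False, lineterminator="\n")
    else:
        frame.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")


def join_reference(event: SourceTable, reference: SourceTable) -> SourceTable:
    """Left-join an event table with its reference dictionary.

    Row count is preserved; descriptive columns from the dictionary are
    appended (nullable).  Events without a dictionary entry keep nulls in
    the descriptive columns and are logged — dropping them would silently
    lose clinical rows.
    """
    rj = event.schema.reference_join
    if rj is None:
        raise SchemaError(f"{event.schema.table_name} has no reference_join")
    if reference.schema.table_name != rj.reference_table:
        raise SchemaError(
            f"expected reference table {rj.reference_table!r}, got {reference.schema.table_name!r}"
        )
    for key in rj.join_key:
        if key not in event.schema.column_names:
            raise SchemaError(f"join key {key!r} absent in {event.schema.table_name}")
        if key not in reference.schema.column_names:
            raise SchemaError(f"join key {key!r} absent in {reference.schema.table_name}")
    desc_cols = [c for c in reference.schema.columns if c.name not in rj.join_key]
    clash = [c.name for c in desc_cols if c.name in event.schema.column_names]
    if clash:
        raise SchemaError(f"descriptive columns {clash} clash with event columns")
    merged = event.frame.merge(
        reference.frame, how="left", on=list(rj.join_key), sort=False, indicator=True
    )
    n_unmatched = int((merged["_merge"] == "left_only").sum())
    merged = merged.drop(columns=["_merge"])
    if n_unmatched:
        for _ in range(n_unmatched):
            logger.warning(
                "table %s: event row without %s dictionary entry kept with null description",
                event.schema.table_name, rj.reference_table,
            )
    joined_schema = TableSchema(
        table_name=event.schema.table_name,
        columns=event.schema.columns
        + tuple(replace(c, nullable=True) for c in desc_cols),
        primary_key=event.schema.primary_key,
        reference_join=None,
    )
    return SourceTable(joined_schema, merged)


@dataclass(frozen=True)
class QueryBatch:
    """A patient batch: extraction restricted to a set of subject ids."""

    subject_ids: frozenset[int]
    tables: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.subject_ids:
            raise SchemaError("QueryBatch requires a non-empty subject_ids set")


def query_batch(
    tables: dict[str, SourceTable], batch: QueryBatch
) -> dict[str, SourceTable]:
    """Restrict every patient-linked table to the batch's subjects.

    Reference dictionaries (no subject_id column) pass through unfiltered.
    """
    wanted = batch.tables or tuple(tables)
    out: dict[str, SourceTable] = {}
    for name in wanted:
        if name not in tables:
            raise UnknownTableError(name)
        tab = tables[name]
        if "subject_id" in tab.schema.column_names:
            mask = tab.frame["subject_id"].isin(list(batch.subject_ids))
            out[name] = SourceTable(tab.schema, tab.frame[mask])
        else:
            out[name] = tab
    return out


# ---------------------------------------------------------------------------
# Default schema registry
# ---------------------------------------------------------------------------

def _ts(name: str, nullable: bool = False) -> ColumnSpec:
    return ColumnSpec(name, "timestamp", nullable)


def _int(name: str, nullable: bool = False) -> ColumnSpec:
    return ColumnSpec(name, "integer", nullable)


def _dec(name: str, nullable: bool = False) -> ColumnSpec:
    return ColumnSpec(name, "decimal", nullable)


def _txt(name: str, nullable: bool = False) -> ColumnSpec:
    return ColumnSpec(name, "text", nullable)


def register_default_schemas() -> dict[str, TableSchema]:
    """Schemas for the 12 core/event tables and 4 reference dictionaries.

    Event↔dictionary pairings: chartevents/procedureevents/inputevents/
    outputevents ↔ d_items, labevents ↔ d_labitems, procedures_icd ↔
    d_icd_procedures, diagnoses_icd ↔ d_icd_diagnoses.  Item dictionaries
    join on ``itemid``; ICD dictionaries on the (icd_code, icd_version)
    pair, mirroring the public MIMIC-IV schema convention.
    """
    icd_key = ("icd_code", "icd_version")
    item_join = ReferenceJoin("d_items", ("itemid",))
    schemas = [
        TableSchema("patients", (
            _int("subject_id"), _txt("gender"), _int("anchor_age"),
            _int("anchor_year"), _ts("dod", nullable=True),
        ), ("subject_id",)),
        TableSchema("admissions", (
            _int("subject_id"), _int("hadm_id"), _ts("admittime"), _ts("dischtime"),
            _txt("admission_type"), _txt("discharge_location", nullable=True),
        ), ("hadm_id",)),
        TableSchema("transfers", (
            _int("subject_id"), _int("hadm_id"), _int("transfer_id"),
            _txt("eventtype"), _txt("careunit", nullable=True),
            _ts("intime"), _ts("outtime", nullable=True),
        ), ("transfer_id",)),
        TableSchema("chartevents", (
            _int("subject_id"), _int("hadm_id"), _ts("charttime"),
            _int("itemid"), _dec("valuenum", nullable=True),
            _txt("valueuom", nullable=True),
        ), ("subject_id", "hadm_id", "charttime", "itemid"), item_join),
        TableSchema("labevents", (
            _int("labevent_id"), _int("subject_id"), _int("hadm_id"),
            _int("itemid"), _ts("charttime"), _dec("valuenum", nullable=True),
            _txt("valueuom", nullable=True),
        ), ("labevent_id",), ReferenceJoin("d_labitems", ("itemid",))),
        TableSchema("procedureevents", (
            _int("orderid"), _int("subject_id"), _int("hadm_id"),
            _ts("starttime"), _ts("endtime", nullable=True), _int("itemid"),
        ), ("orderid",), item_join),
        TableSchema("prescriptions", (
            _int("pharmacy_id"), _int("subject_id"), _int("hadm_id"),
            _txt("drug"), _ts("starttime"), _dec("dose_val_rx", nullable=True),
            _txt("dose_unit_rx", nullable=True),
        ), ("pharmacy_id",)),
        TableSchema("inputevents", (
            _int("orderid"), _int("subject_id"), _int("hadm_id"),
            _ts("starttime", nullable=True), _ts("endtime", nullable=True),
            _int("itemid"), _dec("amount", nullable=True),
            _txt("amountuom", nullable=True),
        ), ("orderid",), item_join),
        TableSchema("microbiologyevents", (
            _int("microevent_id"), _int("subject_id"), _int("hadm_id"),
            _ts("charttime"), _txt("spec_type_desc", nullable=True),
            _txt("test_name"), _txt("org_name", nullable=True),
            _txt("interpretation", nullable=True),
        ), ("microevent_id",)),
        TableSchema("outputevents", (
            _int("subject_id"), _int("hadm_id"), _ts("charttime"),
            _int("itemid"), _dec("value", nullable=True),
            _txt("valueuom", nullable=True),
        ), ("subject_id", "hadm_id", "charttime", "itemid"), item_join),
        TableSchema("procedures_icd", (
            _int("subject_id"), _int("hadm_id"), _int("seq_num"),
            _ts("chartdate"), _txt("icd_code"), _int("icd_version"),
        ), ("subject_id", "hadm_id", "seq_num"),
            ReferenceJoin("d_icd_procedures", icd_key)),
        TableSchema("diagnoses_icd", (
            _int("subject_id"), _int("hadm_id"), _int("seq_num"),
            _txt("icd_code"), _int("icd_version"),
        ), ("subject_id", "hadm_id", "seq_num"),
            ReferenceJoin("d_icd_diagnoses", icd_key)),
        # reference dictionaries
        TableSchema("d_items", (
            _int("itemid"), _txt("label"), _txt("category", nullable=True),
            _txt("unitname", nullable=True),
        ), ("itemid",)),
        TableSchema("d_labitems", (
            _int("itemid"), _txt("label"), _txt("fluid", nullable=True),
            _txt("category", nullable=True),
        ), ("itemid",)),
        TableSchema("d_icd_procedures", (
            _txt("icd_code"), _int("icd_version"), _txt("long_title"),
        ), icd_key),
        TableSchema("d_icd_diagnoses", (
            _txt("icd_code"), _int("icd_version"), _txt("long_title"),
        ), icd_key),
    ]
    registry = {s.table_name: s for s in schemas}
    for s in schemas:
        if s.reference_join and s.reference_join.reference_table not in registry:
            raise SchemaError(
                f"{s.table_name}: reference table {s.reference_join.reference_table!r} unregistered"
            )
    return registry


CORE_EVENT_TABLES: tuple[str, ...] = (
    "patients", "admissions", "transfers", "chartevents", "labevents",
    "procedureevents", "prescriptions", "inputevents", "microbiologyevents",
    "outputevents", "procedures_icd", "diagnoses_icd",
)

REFERENCE_TABLES: tuple[str, ...] = (
    "d_items", "d_labitems", "d_icd_procedures", "d_icd_diagnoses",
)


def schema_from_dict(d: dict) -> TableSchema:
    """Inverse of :meth:`TableSchema.to_dict` (used by staged runs)."""
    rj = d.get("reference_join")
    return TableSchema(
        table_name=d["table_name"],
        columns=tuple(
            ColumnSpec(c["name"], c["kind"], c["nullable"]) for c in d["columns"]
        ),
        primary_key=tuple(d["primary_key"]),
        reference_join=ReferenceJoin(rj["reference_table"], tuple(rj["join_key"])) if rj else None,
    )


def schemas_to_json(schemas: dict[str, TableSchema]) -> str:
    """Serialize a schema registry for documentation purposes."""
    return json.dumps({n: s.to_dict() for n, s in schemas.items()}, indent=2)


def read_cohort_dir(input_dir: str | Path, schemas: Optional[dict[str, TableSchema]] = None) -> dict[str, SourceTable]:
    """Read every registered table from a directory (file name = table name)."""
    schemas = schemas or register_default_schemas()
    input_dir = Path(input_dir)
    tables: dict[str, SourceTable] = {}
    for name, schema in schemas.items():
        path = input_dir / f"{name}.csv"
        if not path.exists() and (input_dir / f"{name}.csv.gz").exists():
            path = input_dir / f"{name}.csv.gz"
        if not path.exists():
            raise ConfigurationError(
                f"required table file {name}.csv not found in {input_dir}"
            )
        tables[name] = read_table(path, schema)
    return tables
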