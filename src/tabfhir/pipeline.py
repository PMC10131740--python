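"""End-to-end orchestration of the five harmonization stages.

The run is a classic extract-transform-load: **query** reads the
hospital tables and merges events with their dictionaries, **map**
translates rows into FHIR R4 resources, **validate** checks them
syntactically, **load** upserts the accepted resources into the
patient-model store, and **export** flattens the store into the 4-key
JSON.  Data rejections never abort a run — they are counted, logged and
reported, so the mapping can be improved iteratively on unseen data;
only configuration and I/O problems raise.

Each stage can also run standalone over a work directory
(:func:`run_stage`), with the staged composition producing the same
counters as one in-memory :func:`run_pipeline`.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigurationError, StageOrderError, UnknownStageError
from .flat import ExportConfig, default_extraction_rules, export_json, load_extraction_rules, select_records
from .mapping import FhirResource, Mapper, default_registry, load_registry, read_ndjson, write_ndjson
from .schemas import (
    CORE_EVENT_TABLES,
    QueryBatch,
    SourceTable,
    join_reference,
    query_batch,
    read_cohort_dir,
    read_table,
    register_default_schemas,
    schema_from_dict,
    write_table,
)
from .store import BaseStore, open_store
from .validation import default_profiles, validate_batch

logger = logging.getLogger("tabfhir")

STAGE_NAMES = ("query", "map", "validate", "load", "export")


@dataclass
class RunConfig:
    input_dir: Path
    store_path: Path
    export_path: Optional[Path] = None
    work_dir: Optional[Path] = None
    registry_path: Optional[Path] = None
    export_config_path: Optional[Path] = None
    extraction_rules_path: Optional[Path] = None
    validation_mode: str = "strict"
    batch_size: Optional[int] = None
    zone_offset: str = "+00:00"
    store_backend: str = "sqlite"
    ndjson: bool = False
    seed: Optional[int] = None  # used only by the generate subcommand

    def __post_init__(self) -> None:
        self.input_dir = Path(self.input_dir)
        self.store_path = Path(self.store_path)
        if self.export_path is None:
            self.export_path = self.store_path.parent / "export.json"
        self.export_path = Path(self.export_path)
        if self.work_dir is None:
            self.work_dir = self.store_path.parent / "work"
        self.work_dir = Path(self.work_dir)
        if self.validation_mode not in ("strict", "lenient"):
            raise ConfigurationError(f"validation_mode must be strict|lenient, got {self.validation_mode!r}")
        if self.batch_size is not None and self.batch_size <= 0:
            raise ConfigurationError("batch_size must be positive when present")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)

    def registry(self):
        return load_registry(self.registry_path) if self.registry_path else default_registry()

    def extraction_rules(self):
        if self.extraction_rules_path:
            return load_extraction_rules(self.extraction_rules_path)
        return default_extraction_rules()

    def export_config(self) -> ExportConfig:
        if self.export_config_path:
            return ExportConfig.from_file(self.export_config_path)
        return ExportConfig()


@dataclass
class RunReport:
    """Per-stage counters, timings and the structured warning/error log."""

    stages: list[dict] = field(default_factory=list)
    counters: dict = field(default_factory=lambda: {
        "rows_read": 0, "resources_mapped": 0, "accepted": 0,
        "rejected": 0, "stored": 0, "records_exported": 0,
    })
    per_table_rows: dict = field(default_factory=dict)
    per_type_stored: dict = field(default_factory=dict)
    log: list[dict] = field(default_factory=list)

    def merge(self, other: "RunReport") -> "RunReport":
        self.stages.extend(other.stages)
        for k, v in other.counters.items():
            self.counters[k] = self.counters.get(k, 0) + v
        self.per_table_rows.update(other.per_table_rows)
        for k, v in other.per_type_stored.items():
            self.per_type_stored[k] = self.per_type_stored.get(k, 0) + v
        self.log.extend(other.log)
        return self

    def check_conservation(self) -> None:
        c = self.counters
        assert c["resources_mapped"] == c["accepted"] + c["rejected"], "mapped != accepted + rejected"
        assert c["stored"] == c["accepted"], "stored != accepted"

    def to_dict(self) -> dict:
        return {
            "stages": self.stages,
            "counters": self.counters,
            "per_table_rows": self.per_table_rows,
            "per_type_stored": self.per_type_stored,
            "log": self.log,
        }

    def write(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")


class _CaptureHandler(logging.Handler):
    """Collects warnings/errors as structured records for the RunReport."""

    def __init__(self, sink: list[dict]):
        super().__init__(level=logging.WARNING)
        self.sink = sink
        self.stage = ""

    def emit(self, record: logging.LogRecord) -> None:
        self.sink.append({
            "stage": self.stage,
            "level": record.levelname,
            "logger": record.name,
            "message": record.getMessage(),
        })


def _timed(report: RunReport, name: str, handler: Optional[_CaptureHandler] = None):
    class _Ctx:
        def __enter__(self):
            if handler:
                handler.stage = name
            self.t0 = time.perf_counter()

        def __exit__(self, *exc):
            report.stages.append({"name": name, "seconds": round(time.perf_counter() - self.t0, 4)})
    return _Ctx()


# ---------------------------------------------------------------------------
# Stage bodies (shared by run_pipeline and run_stage)
# ---------------------------------------------------------------------------

def _stage_query(config: RunConfig) -> dict[str, SourceTable]:
    """Read all tables and merge events with their dictionaries."""
    schemas = register_default_schemas()
    tables = read_cohort_dir(config.input_dir, schemas)
    joined: dict[str, SourceTable] = {}
    for name in CORE_EVENT_TABLES:
        tab = tables[name]
        if tab.schema.reference_join:
            joined[name] = join_reference(tab, tables[tab.schema.reference_join.reference_table])
        else:
            joined[name] = tab
    return joined


def _stage_map(config: RunConfig, joined: dict[str, SourceTable]) -> list[FhirResource]:
    mapper = Mapper(config.registry(), zone_offset=config.zone_offset)
    resources: list[FhirResource] = []
    if config.batch_size:
        subjects = sorted(int(s) for s in joined["patients"].frame["subject_id"].tolist())
        chunks = [subjects[i:i + config.batch_size] for i in range(0, len(subjects), config.batch_size)]
        for chunk in chunks:
            batch_tables = query_batch(joined, QueryBatch(frozenset(chunk)))
            for name in CORE_EVENT_TABLES:
                resources.extend(mapper.map_table(batch_tables[name]))
    else:
        for name in CORE_EVENT_TABLES:
            resources.extend(mapper.map_table(joined[name]))
    return resources


def _stage_load(store: BaseStore, accepted: list[FhirResource]) -> dict[str, int]:
    per_type: dict[str, int] = {}
    for r in accepted:
        store.put(r)
        per_type[r.resource_type] = per_type.get(r.resource_type, 0) + 1
    return per_type


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute query → map → validate → load → export on one input set.

    Idempotent: a second run over the same input leaves store counts
    unchanged.  Returns a complete RunReport; raises only for
    configuration or I/O errors, never for data rejections.
    """
    report = RunReport()
    handler = _CaptureHandler(report.log)
    logger.addHandler(handler)
    try:
        with _timed(report, "query", handler):
            joined = _stage_query(config)
            report.per_table_rows = {n: joined[n].n_rows for n in CORE_EVENT_TABLES}
            report.counters["rows_read"] = sum(report.per_table_rows.values())
        with _timed(report, "map", handler):
            resources = _stage_map(config, joined)
            report.counters["resources_mapped"] = len(resources)
        with _timed(report, "validate", handler):
            accepted, reports = validate_batch(resources, default_profiles(), mode=config.validation_mode)
            report.counters["accepted"] = len(accepted)
            report.counters["rejected"] = sum(1 for r in reports if not r.passed)
        with _timed(report, "load", handler):
            store = open_store(config.store_path, config.store_backend)
            report.per_type_stored = _stage_load(store, accepted)
            report.counters["stored"] = len(accepted)
        with _timed(report, "export", handler):
            records = select_records(store, config.export_config(), config.extraction_rules())
            export_json(records, config.export_path, ndjson=config.ndjson)
            report.counters["records_exported"] = len(records)
        store.close()
    finally:
        logger.removeHandler(handler)
    report.check_conservation()
    return report


# ---------------------------------------------------------------------------
# Staged execution over a work directory
# ---------------------------------------------------------------------------

def run_stage(stage_name: str, config: RunConfig) -> RunReport:
    """Execute exactly one stage, persisting artifacts under work_dir.

    The composition of the five stages in order equals one
    :func:`run_pipeline` call on the same input (same counters).
    """
    if stage_name not in STAGE_NAMES:
        raise UnknownStageError(stage_name)
    report = RunReport()
    handler = _CaptureHandler(report.log)
    logger.addHandler(handler)
    work = config.work_dir
    try:
        if stage_name == "query":
            with _timed(report, "query", handler):
                joined = _stage_query(config)
                qdir = work / "query"
                qdir.mkdir(parents=True, exist_ok=True)
                schema_doc = {}
                for name, tab in joined.items():
                    write_table(tab, qdir / f"{name}.csv")
                    schema_doc[name] = tab.schema.to_dict()
                (qdir / "_schemas.json").write_text(json.dumps(schema_doc), encoding="utf-8")
                report.per_table_rows = {n: joined[n].n_rows for n in CORE_EVENT_TABLES}
                report.counters["rows_read"] = sum(report.per_table_rows.values())
        elif stage_name == "map":
            qdir = work / "query"
            if not (qdir / "_schemas.json").exists():
                raise StageOrderError("map requires the query stage artifacts (work/query)")
            with _timed(report, "map", handler):
                schema_doc = json.loads((qdir / "_schemas.json").read_text(encoding="utf-8"))
                joined = {
                    name: read_table(qdir / f"{name}.csv", schema_from_dict(d))
                    for name, d in schema_doc.items()
                }
                resources = _stage_map(config, joined)
                write_ndjson(resources, work / "map" / "resources.ndjson")
                report.counters["resources_mapped"] = len(resources)
        elif stage_name == "validate":
            src = work / "map" / "resources.ndjson"
            if not src.exists():
                raise StageOrderError("validate requires the map stage artifact (resources.ndjson)")
            with _timed(report, "validate", handler):
                resources = read_ndjson(src)
                accepted, reports = validate_batch(resources, default_profiles(), mode=config.validation_mode)
                vdir = work / "validate"
                write_ndjson(accepted, vdir / "accepted.ndjson")
                with open(vdir / "reports.ndjson", "wt", encoding="utf-8") as fh:
                    for rep in reports:
                        fh.write(json.dumps(rep.to_dict(), ensure_ascii=False) + "\n")
                report.counters["accepted"] = len(accepted)
                report.counters["rejected"] = sum(1 for r in reports if not r.passed)
        elif stage_name == "load":
            src = work / "validate" / "accepted.ndjson"
            if not src.exists():
                raise StageOrderError("load requires the validate stage artifact (accepted.ndjson)")
            with _timed(report, "load", handler):
                accepted = read_ndjson(src)
                store = open_store(config.store_path, config.store_backend)
                report.per_type_stored = _stage_load(store, accepted)
                report.counters["stored"] = len(accepted)
                store.close()
        else:  # export
            with _timed(report, "export", handler):
                store = open_store(config.store_path, config.store_backend)
                if store.count() == 0:
                    logger.warning("export: patient-model store is empty; writing an empty export")
                records = select_records(store, config.export_config(), config.extraction_rules())
                export_json(records, config.export_path, ndjson=config.ndjson)
                report.counters["records_exported"] = len(records)
                store.close()
    finally:
        logger.removeHandler(handler)
    return report
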