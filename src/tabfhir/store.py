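"""Patient-model document store: validated resources grouped by type.

Each resource is one JSON document keyed by (resource_type, resource_id).
Writes are idempotent upserts — harmonizing the same data twice leaves
one document per logical resource, and a changed document replaces the
old one with a logged notice.  Insertion order is preserved and exposed
so exports are deterministic.

Two interchangeable backends behind the same contract: an embedded
single-file SQLite store (default) and a directory backend laying out
``<store>/<ResourceType>/<id>.json`` for direct inspection.  A server
database (the production choice for this kind of warehouse) would slot
in behind the same interface.
"""

from __future__ import annotations

import json
import logging
import sqlite3
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Iterator, Optional

from .errors import StorageError
from .mapping import FhirResource

logger = logging.getLogger("tabfhir.store")

Predicate = Callable[[FhirResource], bool]


@dataclass(frozen=True)
class StoredDocument:
    resource_type: str
    resource_id: str
    document: str
    inserted_at: str


def _serialize(resource: FhirResource) -> str:
    try:
        return json.dumps(resource.body, ensure_ascii=False, sort_keys=False)
    except (TypeError, ValueError) as exc:
        raise StorageError(f"cannot serialize {resource.resource_type}/{resource.id}: {exc}")


def _now() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="seconds")


class BaseStore:
    """Contract shared by both backends."""

    def put(self, resource: FhirResource) -> StoredDocument:
        raise NotImplementedError

    def get_by_type(self, resource_type: str, predicate: Optional[Predicate] = None) -> list[FhirResource]:
        raise NotImplementedError

    def count(self, resource_type: Optional[str] = None) -> int:
        raise NotImplementedError

    def types(self) -> list[str]:
        raise NotImplementedError

    def iter_all(self) -> Iterator[FhirResource]:
        raise NotImplementedError

    def close(self) -> None:  # pragma: no cover - trivial
        pass

    # -- conveniences ----------------------------------------------------
    def get_for_subject(self, resource_type: str, subject_reference: str) -> list[FhirResource]:
        """All documents of a type whose subject points at one patient."""
        from .paths import get_path

        def pred(r: FhirResource) -> bool:
            return get_path(r.body, "subject.reference") == subject_reference

        return self.get_by_type(resource_type, pred)

    def dump_ndjson(self, out_dir: str | Path) -> None:
        """Bulk dump, one NDJSON file per resource type."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rtype in self.types():
            with open(out_dir / f"{rtype}.ndjson", "wt", encoding="utf-8") as fh:
                for r in self.get_by_type(rtype):
                    fh.write(json.dumps(r.body, ensure_ascii=False) + "\n")

    def load_ndjson(self, in_dir: str | Path) -> int:
        in_dir = Path(in_dir)
        n = 0
        for path in sorted(in_dir.glob("*.ndjson")):
            with open(path, "rt", encoding="utf-8") as fh:
                for line in fh:
                    if line.strip():
                        self.put(FhirResource.from_body(json.loads(line)))
                        n += 1
        return n


class SqliteStore(BaseStore):
    """Embedded single-file store; documents in a keyed relational table."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self._conn = sqlite3.connect(str(self.path))
        self._conn.execute(
            """
            CREATE TABLE IF NOT EXISTS resources (
                seq INTEGER PRIMARY KEY AUTOINCREMENT,
                resource_type TEXT NOT NULL,
                resource_id TEXT NOT NULL,
                document TEXT NOT NULL,
                inserted_at TEXT NOT NULL,
                UNIQUE (resource_type, resource_id)
            )
            """
        )
        self._conn.commit()

    def put(self, resource: FhirResource) -> StoredDocument:
        doc = _serialize(resource)
        ts = _now()
        cur = self._conn.execute(
            "SELECT document FROM resources WHERE resource_type=? AND resource_id=?",
            (resource.resource_type, resource.id),
        )
        row = cur.fetchone()
        if row is None:
            self._conn.execute(
                "INSERT INTO resources (resource_type, resource_id, document, inserted_at)"
                " VALUES (?,?,?,?)",
                (resource.resource_type, resource.id, doc, ts),
            )
        elif row[0] != doc:
            logger.info(
                "store: replacing changed document %s/%s", resource.resource_type, resource.id
            )
            self._conn.execute(
                "UPDATE resources SET document=?, inserted_at=? WHERE resource_type=? AND resource_id=?",
                (doc, ts, resource.resource_type, resource.id),
            )
        self._conn.commit()
        return StoredDocument(resource.resource_type, resource.id, doc, ts)

    def get_by_type(self, resource_type: str, predicate: Optional[Predicate] = None) -> list[FhirResource]:
        cur = self._conn.execute(
            "SELECT document FROM resources WHERE resource_type=? ORDER BY seq",
            (resource_type,),
        )
        out = [FhirResource.from_body(json.loads(r[0])) for r in cur.fetchall()]
        if predicate is not None:
            out = [r for r in out if predicate(r)]
        return out

    def count(self, resource_type: Optional[str] = None) -> int:
        if resource_type is None:
            cur = self._conn.execute("SELECT COUNT(*) FROM resources")
        else:
            cur = self._conn.execute(
                "SELECT COUNT(*) FROM resources WHERE resource_type=?", (resource_type,)
            )
        return int(cur.fetchone()[0])

    def types(self) -> list[str]:
        cur = self._conn.execute(
            "SELECT resource_type FROM resources GROUP BY resource_type ORDER BY MIN(seq)"
        )
        return [r[0] for r in cur.fetchall()]

    def iter_all(self) -> Iterator[FhirResource]:
        cur = self._conn.execute("SELECT document FROM resources ORDER BY seq")
        for (doc,) in cur.fetchall():
            yield FhirResource.from_body(json.loads(doc))

    def close(self) -> None:
        self._conn.close()


class DirectoryStore(BaseStore):
    """One JSON file per resource under a per-type folder, for inspection.

    Insertion order lives in an ``_index.json`` manifest at the root.
    """

    def __init__(self, path: str | Path):
        self.root = Path(path)
        self.root.mkdir(parents=True, exist_ok=True)
        self._index_path = self.root / "_index.json"
        if not self._index_path.exists():
            self._write_index([])

    def _read_index(self) -> list[list[str]]:
        return json.loads(self._index_path.read_text(encoding="utf-8"))

    def _write_index(self, index: list[list[str]]) -> None:
        self._index_path.write_text(json.dumps(index, indent=0), encoding="utf-8")

    def _doc_path(self, rtype: str, rid: str) -> Path:
        return self.root / rtype / f"{rid}.json"

    def put(self, resource: FhirResource) -> StoredDocument:
        doc = _serialize(resource)
        ts = _now()
        path = self._doc_path(resource.resource_type, resource.id)
        path.parent.mkdir(parents=True, exist_ok=True)
        index = self._read_index()
        key = [resource.resource_type, resource.id]
        if path.exists():
            if path.read_text(encoding="utf-8") != doc:
                logger.info(
                    "store: replacing changed document %s/%s",
                    resource.resource_type, resource.id,
                )
                path.write_text(doc, encoding="utf-8")
        else:
            path.write_text(doc, encoding="utf-8")
            index.append(key + [ts])
            self._write_index(index)
        return StoredDocument(resource.resource_type, resource.id, doc, ts)

    def get_by_type(self, resource_type: str, predicate: Optional[Predicate] = None) -> list[FhirResource]:
        out = []
        for rtype, rid, _ts in self._read_index():
            if rtype != resource_type:
                continue
            body = json.loads(self._doc_path(rtype, rid).read_text(encoding="utf-8"))
            out.append(FhirResource.from_body(body))
        if predicate is not None:
            out = [r for r in out if predicate(r)]
        return out

    def count(self, resource_type: Optional[str] = None) -> int:
        index = self._read_index()
        if resource_type is None:
            return len(index)
        return sum(1 for rtype, _rid, _ts in index if rtype == resource_type)

    def types(self) -> list[str]:
        seen: list[str] = []
        for rtype, _rid, _ts in self._read_index():
            if rtype not in seen:
                seen.append(rtype)
        return seen

    def iter_all(self) -> Iterator[FhirResource]:
        for rtype, rid, _ts in self._read_index():
            body = json.loads(self._doc_path(rtype, rid).read_text(encoding="utf-8"))
            yield FhirResource.from_body(body)


def open_store(path: str | Path, backend: str = "sqlite") -> BaseStore:
    if backend == "sqlite":
        return SqliteStore(path)
    if backend == "directory":
        return DirectoryStore(path)
    raise StorageError(f"unknown store backend {backend!r}")
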