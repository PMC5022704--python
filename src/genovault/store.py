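"""Single-file embedded object store with lazy minimal views.

The store keeps one SQLite table per record kind (schemas in
:mod:`genovault.model`).  Queries go through a single entry point,
:meth:`Store.get`, which yields :class:`LazyRecord` objects in *minimal
view*: only the light columns are fetched.  Heavy fields (chromosome and
transcript sequences, protein sequences) are fetched by a second
single-row query on first attribute access, exactly once per record —
inflation is monotone and idempotent.

Every loaded record is a session singleton: two ``get()`` calls resolving
the same ``(kind, id)`` return the *same* Python object, so field
inflation through one handle is visible through every other.  The cache is
unbounded and per-session; sessions are single-threaded by contract.

The database file is the complete state: copying it is the supported
backup/sharing mechanism, and any SQLite client can read it directly.
Index creation is under user control via :meth:`Store.ensure_global_index`
/ :meth:`Store.drop_global_index`; indexes change query speed, never query
results.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterator, Mapping

from .errors import FieldError, NotFoundError, SchemaError
from .model import KINDS, KindSchema, decode_value, encode_value, sql_type

# FilterSpec comparator suffixes: {"start__lt": 100} -> start < 100.
_COMPARATORS = {
    "lt": "{} < ?",
    "gt": "{} > ?",
    "prefix": "{} LIKE ? ESCAPE '\\'",
    "eq": "{} = ?",
}


@dataclass(frozen=True)
class IndexHandle:
    """Names one user-controlled global index on (kind, field)."""

    kind: str
    field: str

    @property
    def name(self) -> str:
        return f"{self.kind}.{self.field}"

    @property
    def sql_name(self) -> str:
        return f"gidx_{self.kind}_{self.field}"


class LazyRecord:
    """A store-backed record in minimal view.

    Light fields are plain attributes; accessing an unloaded heavy field
    triggers a one-row fetch (recorded on the store's load-event log) and
    permanently adds the field to ``loaded_fields``.
    """

    __slots__ = ("_store", "kind", "id", "_values", "loaded_fields")

    def __init__(self, store: "Store", kind: str, values: dict[str, Any]):
        object.__setattr__(self, "_store", store)
        object.__setattr__(self, "kind", kind)
        object.__setattr__(self, "id", values["id"])
        object.__setattr__(self, "_values", values)
        object.__setattr__(self, "loaded_fields", set(values))

    @property
    def heavy_fields(self) -> frozenset[str]:
        return KINDS[self.kind].heavy

    def __getattr__(self, name: str):
        # only called when normal lookup fails, i.e. for schema fields
        values = object.__getattribute__(self, "_values")
        if name in values:
            return values[name]
        schema = KINDS[self.kind]
        if name in schema.fields:  # heavy, not yet loaded
            value = self._store._load_heavy_field(self, name)
            values[name] = value
            self.loaded_fields.add(name)
            return value
        raise FieldError(f"{self.kind} has no field {name!r}")

    def __setattr__(self, name, value):
        raise AttributeError("records are read-only; mutate via the store")

    def __repr__(self) -> str:
        return f"<{self.kind} {self.id} loaded={sorted(self.loaded_fields)}>"


class Store:
    """One embedded database file plus the session singleton cache."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.connection = sqlite3.connect(str(self.path))
        self.connection.execute("PRAGMA foreign_keys = ON")
        self._cache: dict[tuple[str, str], LazyRecord] = {}
        #: (kind, id, field) per heavy-field fetch; laziness is asserted
        #: against this log.
        self.load_events: list[tuple[str, str, str]] = []
        self._create_tables()

    # -- schema -----------------------------------------------------------

    def _create_tables(self) -> None:
        for schema in KINDS.values():
            cols = ", ".join(
                f"{f} {sql_type(f)}" + (" PRIMARY KEY" if f == "id" else "")
                for f in schema.fields
            )
            self.connection.execute(
                f"CREATE TABLE IF NOT EXISTS {schema.table} ({cols})"
            )
        self.connection.commit()

    @staticmethod
    def _schema(kind: str) -> KindSchema:
        try:
            return KINDS[kind]
        except KeyError:
            raise SchemaError(
                f"unknown record kind {kind!r}; known: {sorted(KINDS)}"
            ) from None

    # -- queries ----------------------------------------------------------

    def get(
        self, kind: str, filters: Mapping[str, Any] | None = None, **kw: Any
    ) -> Iterator[LazyRecord]:
        """The universal query entry point.

        *filters* is a conjunction of ``field`` / ``field__lt`` /
        ``field__gt`` / ``field__prefix`` constraints (bare field means
        equality); an empty filter yields every record of the kind.
        Records are yielded in minimal view, in primary-key order.
        """
        schema = self._schema(kind)
        spec = dict(filters or {})
        spec.update(kw)
        where, params = self._compile_filter(schema, spec)
        cols = ", ".join(schema.light)
        sql = f"SELECT {cols} FROM {schema.table}"
        if where:
            sql += f" WHERE {where}"
        sql += " ORDER BY id"
        for row in self.connection.execute(sql, params):
            values = {
                f: decode_value(schema, f, v) for f, v in zip(schema.light, row)
            }
            key = (kind, values["id"])
            record = self._cache.get(key)
            if record is None:
                record = LazyRecord(self, kind, values)
                self._cache[key] = record
            yield record

    def _compile_filter(self, schema: KindSchema, spec: Mapping[str, Any]):
        clauses, params = [], []
        for key, value in spec.items():
            field_name, _, op = key.partition("__")
            op = op or "eq"
            if field_name not in schema.fields:
                raise FieldError(
                    f"{schema.kind} has no field {field_name!r}"
                )
            if op not in _COMPARATORS:
                raise FieldError(f"unknown comparator {op!r} in {key!r}")
            if op == "prefix":
                escaped = (
                    str(value).replace("\\", "\\\\")
                    .replace("%", "\\%").replace("_", "\\_")
                )
                params.append(escaped + "%")
            else:
                params.append(encode_value(schema, field_name, value))
            clauses.append(_COMPARATORS[op].format(field_name))
        return " AND ".join(clauses), params

    def get_one(self, kind: str, record_id: str) -> LazyRecord:
        """Fetch exactly one record by primary key or raise NotFoundError."""
        for record in self.get(kind, {"id": record_id}):
            return record
        raise NotFoundError(f"{kind} {record_id!r} not found")

    def count(self, kind: str, filters: Mapping[str, Any] | None = None) -> int:
        return sum(1 for _ in self.get(kind, filters))

    # -- lazy inflation ---------------------------------------------------

    def _load_heavy_field(self, record: LazyRecord, field_name: str):
        schema = self._schema(record.kind)
        row = self.connection.execute(
            f"SELECT {field_name} FROM {schema.table} WHERE id = ?",
            (record.id,),
        ).fetchone()
        if row is None:  # pragma: no cover - record deleted underneath
            raise NotFoundError(f"{record.kind} {record.id!r} vanished from store")
        self.load_events.append((record.kind, record.id, field_name))
        return decode_value(schema, field_name, row[0])

    def load_count(self, kind: str | None = None, field: str | None = None) -> int:
        """Number of heavy-field load events, optionally filtered."""
        return sum(
            1
            for (k, _i, f) in self.load_events
            if (kind is None or k == kind) and (field is None or f == field)
        )

    # -- writes (used by importers and fixtures) --------------------------

    def insert(self, kind: str, values: Mapping[str, Any]) -> None:
        self.insert_many(kind, [values])

    def insert_many(self, kind: str, rows) -> None:
        schema = self._schema(kind)
        rows = list(rows)
        for values in rows:
            unknown = set(values) - set(schema.fields)
            if unknown:
                raise FieldError(f"{kind} has no fields {sorted(unknown)}")
        cols = schema.fields
        sql = (
            f"INSERT INTO {schema.table} ({', '.join(cols)}) "
            f"VALUES ({', '.join('?' for _ in cols)})"
        )
        self.connection.executemany(
            sql,
            [
                tuple(encode_value(schema, f, values.get(f)) for f in cols)
                for values in rows
            ],
        )

    def delete_where(self, kind: str, filters: Mapping[str, Any]) -> None:
        schema = self._schema(kind)
        where, params = self._compile_filter(schema, filters)
        sql = f"DELETE FROM {schema.table}"
        if where:
            sql += f" WHERE {where}"
        self.connection.execute(sql, params)
        for key in [k for k in self._cache if k[0] == kind]:
            del self._cache[key]

    def commit(self) -> None:
        self.connection.commit()

    # -- user-controlled indexes ------------------------------------------

    def ensure_global_index(self, kind: str, field: str) -> IndexHandle:
        """Create the (kind, field) index if absent; idempotent."""
        schema = self._schema(kind)
        if field not in schema.fields:
            raise FieldError(f"{kind} has no field {field!r}")
        handle = IndexHandle(kind, field)
        self.connection.execute(
            f"CREATE INDEX IF NOT EXISTS {handle.sql_name} "
            f"ON {schema.table} ({field})"
        )
        self.connection.commit()
        return handle

    def drop_global_index(self, kind: str, field: str) -> None:
        """Drop the (kind, field) index; a no-op when it does not exist."""
        schema = self._schema(kind)
        if field not in schema.fields:
            raise FieldError(f"{kind} has no field {field!r}")
        self.connection.execute(
            f"DROP INDEX IF EXISTS {IndexHandle(kind, field).sql_name}"
        )
        self.connection.commit()

    def list_global_indexes(self) -> list[IndexHandle]:
        rows = self.connection.execute(
            "SELECT name FROM sqlite_master WHERE type='index' "
            "AND name LIKE 'gidx_%'"
        ).fetchall()
        out = []
        for (name,) in rows:
            _, kind, field = name.split("_", 2)
            out.append(IndexHandle(kind, field))
        return out

    # -- lifecycle --------------------------------------------------------

    def close(self) -> None:
        self.connection.commit()
        self.connection.close()
        self._cache.clear()

    def __enter__(self) -> "Store":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Store {self.path}>"
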