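"""Persistent data model on an embedded SQLite store.

Layout mirrors the registration-system entity model:

* ``structures`` — unique, immutable chemical structures keyed by
  InChIKey (unique constraint), with stored molecular weight and the
  screening fingerprint.
* one table per registered *compound type* (table-per-concrete-class:
  each type stores and searches independently) plus a composition table
  linking compounds to structures with an optional percentage.
* one table per registered *containable type* (batch / lot), paired with
  a compound type.
* ``containers`` — bar-coded physical vessels, exactly one containable
  each, barcode unique and not null.
* ``roles`` / ``users`` — read-role vocabulary for optional row filtering.
* ``search_count_cache`` — persisted total-count cache for paged queries.

Audit metadata (created/modified by+at, optimistic-lock version) is carried
by every entity table. All uniqueness is enforced by store-level
constraints, not only in application code.
"""

from __future__ import annotations

import os
import sqlite3
from contextlib import contextmanager
from dataclasses import dataclass, field

from .errors import StoreError

__all__ = ["Store", "CompoundType", "ContainableType", "META_COLUMNS"]

META_COLUMNS = ("created_by", "created_at", "modified_by", "modified_at",
                "version")

_META_DDL = """\
    created_by TEXT NOT NULL,
    created_at TEXT NOT NULL,
    modified_by TEXT NOT NULL,
    modified_at TEXT NOT NULL,
    version INTEGER NOT NULL DEFAULT 0"""

_VALID_AFFINITIES = {"TEXT", "INTEGER", "REAL"}


@dataclass(frozen=True)
class CompoundType:
    """A registered concrete compound class with its own table."""

    name: str
    extra_columns: tuple[tuple[str, str], ...] = ()

    @property
    def table(self) -> str:
        return f"compound_{self.name}"

    @property
    def composition_table(self) -> str:
        return f"composition_{self.name}"


@dataclass(frozen=True)
class ContainableType:
    """A registered batch/lot class, paired with a compound type."""

    name: str
    compound_type: str
    extra_columns: tuple[tuple[str, str], ...] = ()

    @property
    def table(self) -> str:
        return f"containable_{self.name}"


def _check_columns(cols) -> tuple[tuple[str, str], ...]:
    out = []
    for name, affinity in (cols or {}).items():
        affinity = affinity.upper()
        if affinity not in _VALID_AFFINITIES:
            raise ValueError(f"unsupported column affinity {affinity!r}")
        if not name.isidentifier():
            raise ValueError(f"invalid column name {name!r}")
        out.append((name, affinity))
    return tuple(out)


class Store:
    """SQLite-backed store; ``path`` may be ``":memory:"``."""

    def __init__(self, path: str = ":memory:"):
        self.path = path
        if path != ":memory:":
            directory = os.path.dirname(os.path.abspath(path))
            if not os.path.isdir(directory) or not os.access(directory,
                                                             os.W_OK):
                raise StoreError(f"store target not writable: {path}")
        try:
            self.conn = sqlite3.connect(path)
        except sqlite3.Error as exc:
            raise StoreError(f"cannot open store at {path}: {exc}") from exc
        self.conn.row_factory = sqlite3.Row
        self.conn.isolation_level = None  # explicit transactions
        self.conn.execute("PRAGMA foreign_keys = ON")
        self.compound_types: dict[str, CompoundType] = {}
        self.containable_types: dict[str, ContainableType] = {}
        self._in_txn = False

    # -- type registry -----------------------------------------------------

    def register_compound_type(self, name: str,
                               extra_columns: dict[str, str] | None = None
                               ) -> CompoundType:
        ct = CompoundType(name, _check_columns(extra_columns))
        self.compound_types[name] = ct
        return ct

    def register_containable_type(self, name: str, compound_type: str,
                                  extra_columns: dict[str, str] | None = None
                                  ) -> ContainableType:
        if compound_type not in self.compound_types:
            raise ValueError(f"unknown compound type {compound_type!r}")
        ct = ContainableType(name, compound_type,
                             _check_columns(extra_columns))
        self.containable_types[name] = ct
        return ct

    # -- schema ------------------------------------------------------------

    def ddl(self) -> str:
        """Full schema DDL for the registered types (idempotent)."""
        stmts = [f"""\
CREATE TABLE IF NOT EXISTS structures (
    id INTEGER PRIMARY KEY,
    structure_text TEXT NOT NULL,
    structure_key TEXT NOT NULL UNIQUE,
    mol_weight REAL NOT NULL,
    fp_bits BLOB,
    fp_popcount INTEGER,
    fp_params TEXT,
{_META_DDL}
);""",
                 "CREATE INDEX IF NOT EXISTS ix_structures_mw "
                 "ON structures (mol_weight);",
                 """\
CREATE TABLE IF NOT EXISTS roles (
    id INTEGER PRIMARY KEY,
    name TEXT NOT NULL UNIQUE
);""",
                 """\
CREATE TABLE IF NOT EXISTS users (
    id INTEGER PRIMARY KEY,
    name TEXT NOT NULL UNIQUE
);""",
                 """\
CREATE TABLE IF NOT EXISTS user_roles (
    user_name TEXT NOT NULL,
    role_name TEXT NOT NULL,
    UNIQUE (user_name, role_name)
);""",
                 """\
CREATE TABLE IF NOT EXISTS search_count_cache (
    cache_key TEXT PRIMARY KEY,
    entity_kind TEXT NOT NULL,
    total_count INTEGER NOT NULL
);"""]
        for ct in self.compound_types.values():
            extra = "".join(f",\n    {n} {aff}" for n, aff in
                            ct.extra_columns)
            stmts.append(f"""\
CREATE TABLE IF NOT EXISTS {ct.table} (
    id INTEGER PRIMARY KEY,
    compound_name TEXT,
    cas TEXT,
    read_role TEXT,
{_META_DDL}{extra}
);""")
            stmts.append(f"CREATE INDEX IF NOT EXISTS ix_{ct.table}_cas "
                         f"ON {ct.table} (cas);")
            stmts.append(f"CREATE INDEX IF NOT EXISTS ix_{ct.table}_name "
                         f"ON {ct.table} (compound_name);")
            stmts.append(f"""\
CREATE TABLE IF NOT EXISTS {ct.composition_table} (
    id INTEGER PRIMARY KEY,
    compound_id INTEGER NOT NULL REFERENCES {ct.table} (id)
        ON DELETE CASCADE,
    structure_id INTEGER NOT NULL REFERENCES structures (id),
    percentage REAL
        CHECK (percentage IS NULL
               OR (percentage > 0 AND percentage <= 100)),
    UNIQUE (compound_id, structure_id)
);""")
            stmts.append(
                f"CREATE INDEX IF NOT EXISTS ix_{ct.composition_table}_sid "
                f"ON {ct.composition_table} (structure_id);")
        for nt in self.containable_types.values():
            parent = self.compound_types[nt.compound_type]
            extra = "".join(f",\n    {n} {aff}" for n, aff in
                            nt.extra_columns)
            stmts.append(f"""\
CREATE TABLE IF NOT EXISTS {nt.table} (
    id INTEGER PRIMARY KEY,
    compound_id INTEGER NOT NULL REFERENCES {parent.table} (id),
    read_role TEXT,
{_META_DDL}{extra}
);""")
        if self.containable_types:
            stmts.append(f"""\
CREATE TABLE IF NOT EXISTS containers (
    id INTEGER PRIMARY KEY,
    barcode TEXT NOT NULL UNIQUE,
    containable_type TEXT NOT NULL,
    containable_id INTEGER NOT NULL,
{_META_DDL}
);""")
        return "\n".join(stmts)

    def init_schema(self) -> None:
        """Create all tables, constraints and indices; idempotent."""
        try:
            self.conn.executescript(self.ddl())
        except sqlite3.Error as exc:
            raise StoreError(f"schema initialization failed: {exc}") from exc

    # -- transactions ------------------------------------------------------

    @contextmanager
    def transaction(self):
        """Single-writer transaction; rolls back on any exception.
        Re-entrant calls join the enclosing transaction."""
        if self._in_txn:
            yield self.conn
            return
        self._in_txn = True
        self.conn.execute("BEGIN IMMEDIATE")
        try:
            yield self.conn
        except BaseException:
            self.conn.execute("ROLLBACK")
            raise
        finally:
            self._in_txn = False
        self.conn.execute("COMMIT")

    # -- statistics --------------------------------------------------------

    def _tables(self) -> list[str]:
        out = ["structures"]
        for ct in self.compound_types.values():
            out += [ct.table, ct.composition_table]
        out += [nt.table for nt in self.containable_types.values()]
        if self.containable_types:
            out.append("containers")
        return out

    _INDEXED = {
        "structures": ("mol_weight",),
    }

    def table_stats(self, sample_size: int = 256) -> dict:
        """Row counts (exact) and, for indexed columns, exact distinct-value
        counts plus a deterministic row-spread value sample used for
        prefix-selectivity estimation."""
        stats: dict[str, dict] = {}
        for table in self._tables():
            rows = self.conn.execute(
                f"SELECT COUNT(*) FROM {table}").fetchone()[0]
            cols: dict[str, dict] = {}
            indexed = self._INDEXED.get(table, ())
            if table.startswith("compound_"):
                indexed = ("cas", "compound_name")
            elif table == "containers":
                indexed = ("barcode",)
            for col in indexed:
                distinct = self.conn.execute(
                    f"SELECT COUNT(DISTINCT {col}) FROM {table} "
                    f"WHERE {col} IS NOT NULL").fetchone()[0]
                step = max(1, rows // sample_size)
                sample = [r[0] for r in self.conn.execute(
                    f"SELECT {col} FROM {table} WHERE {col} IS NOT NULL "
                    f"AND id % ? = 0 LIMIT ?", (step, sample_size))]
                cols[col] = {"distinct": distinct, "exact": True,
                             "sample": sample}
            stats[table] = {"rows": rows, "exact": True, "columns": cols}
        return stats

    def close(self) -> None:
        self.conn.close()
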