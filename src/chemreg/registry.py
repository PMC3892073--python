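"""Transactional service layer: create/update/delete with structure
deduplication and immutability, uniqueness policies, optimistic locking
and pre-save hooks.

Stored structures are unique (one row per structure key) and immutable:
editing a compound never mutates a structure row — the edited component is
resolved to an existing row by key or a new row is inserted, and the old
row remains unchanged. Deleting a compound does not garbage-collect
orphaned structures.

Duplicate components within one compound (e.g. a di-salt carrying two
bromide counter-ions) collapse onto a single composition per distinct
structure, matching the store's one-membership-per-structure constraint.

Uniqueness of *compounds* is a pluggable policy: ``none`` (default,
permissive), ``by_cas``, or ``by_exact_composition`` (identical sets of
structure keys).
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from typing import Callable

from .chem import (Molecule, canonical_form, molecular_weight,
                   parse_structure, split_components, structure_key)
from .errors import (ConcurrentModificationError, ConstraintError,
                     NotFoundError, ParseError, UniquenessError)
from .matching import DEFAULT_PARAMS, FingerprintParams, fingerprint
from .security import SecurityContext, guard_write
from .store import Store

__all__ = ["CompoundDraft", "ContainableDraft", "ContainerDraft",
           "SaveOutcome", "Registry"]


def _now() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="microseconds")


@dataclass
class CompoundDraft:
    """Unsaved compound; compositions are (structure text, percentage)
    pairs. A single text with disconnected components is expanded into one
    composition per component with percentages unset."""

    compositions: list[tuple[str, float | None]]
    compound_name: str | None = None
    cas: str | None = None
    read_role: str | None = None
    extra: dict = field(default_factory=dict)
    id: int | None = None
    expected_version: int | None = None


@dataclass
class ContainableDraft:
    compound_id: int
    read_role: str | None = None
    extra: dict = field(default_factory=dict)
    id: int | None = None
    expected_version: int | None = None


@dataclass
class ContainerDraft:
    barcode: str | None
    containable_type: str
    containable_id: int
    id: int | None = None
    expected_version: int | None = None


@dataclass
class SaveOutcome:
    record: dict
    structures_created: int
    structures_reused: int


class Registry:
    """Service facade over a :class:`~chemreg.store.Store`."""

    def __init__(self, store: Store,
                 security: SecurityContext | None = None,
                 fp_params: FingerprintParams = DEFAULT_PARAMS,
                 store_canonical: bool = True):
        self.store = store
        self.security = security or SecurityContext.disabled()
        self.fp_params = fp_params
        self.store_canonical = store_canonical
        self._hooks: dict[str, Callable] = {}
        self._uniqueness: dict[str, str | Callable] = {}

    # -- configuration -----------------------------------------------------

    def register_pre_save_hook(self, entity_kind: str, hook: Callable
                               ) -> None:
        """Register ``hook(draft) -> draft | None`` to run before every
        create and update of ``entity_kind`` (a compound or containable
        type name). One hook per kind; later registration replaces."""
        self._hooks[entity_kind] = hook

    def set_uniqueness_policy(self, compound_type: str,
                              policy: str | Callable) -> None:
        if isinstance(policy, str) and policy not in (
                "none", "by_cas", "by_exact_composition"):
            raise ValueError(f"unknown uniqueness policy {policy!r}")
        self._uniqueness[compound_type] = policy

    def _run_hook(self, kind: str, draft):
        hook = self._hooks.get(kind)
        if hook is None:
            return draft
        return hook(draft) or draft

    # -- roles / users -----------------------------------------------------

    def add_role(self, name: str) -> None:
        with self.store.transaction() as conn:
            try:
                conn.execute("INSERT INTO roles (name) VALUES (?)", (name,))
            except sqlite3.IntegrityError as exc:
                raise ConstraintError(f"role {name!r} exists") from exc

    def add_user(self, name: str, roles: list[str] | None = None) -> None:
        with self.store.transaction() as conn:
            conn.execute("INSERT OR IGNORE INTO users (name) VALUES (?)",
                         (name,))
            for role in roles or []:
                conn.execute(
                    "INSERT OR IGNORE INTO user_roles (user_name, role_name)"
                    " VALUES (?, ?)", (name, role))

    def user_roles(self, name: str | None) -> frozenset[str]:
        if name is None:
            return frozenset()
        rows = self.store.conn.execute(
            "SELECT role_name FROM user_roles WHERE user_name = ?", (name,))
        return frozenset(r[0] for r in rows)

    # -- structure resolution ----------------------------------------------

    def _resolve_structure(self, conn, component: Molecule, actor: str
                           ) -> tuple[int, bool]:
        """Return (structure id, created?) for one connected component,
        reusing the existing row with the same structure key if any."""
        key = structure_key(component).key
        row = conn.execute(
            "SELECT id FROM structures WHERE structure_key = ?",
            (key,)).fetchone()
        if row:
            return row[0], False
        text = (canonical_form(component) if self.store_canonical
                else component.source_text)
        fp = fingerprint(component, self.fp_params)
        now = _now()
        cur = conn.execute(
            "INSERT INTO structures (structure_text, structure_key, "
            "mol_weight, fp_bits, fp_popcount, fp_params, created_by, "
            "created_at, modified_by, modified_at, version) "
            "VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?, ?, 0)",
            (text, key, molecular_weight(component), fp.to_bytes(),
             fp.popcount, fp.params_id, actor, now, actor, now))
        return cur.lastrowid, True

    def _expand_compositions(self, draft: CompoundDraft
                             ) -> list[tuple[Molecule, float | None]]:
        expanded: list[tuple[Molecule, float | None]] = []
        if not draft.compositions:
            raise ConstraintError("a compound needs at least one component")
        for text, pct in draft.compositions:
            mol = parse_structure(text)
            parts = split_components(mol)
            if len(parts) == 1:
                expanded.append((parts[0], pct))
            else:
                # a multi-component entry is a mixture; relative amounts
                # of the pieces are unknown, so percentages stay unset
                expanded.extend((p, None) for p in parts)
        return expanded

    def _check_uniqueness(self, conn, type_name: str, draft: CompoundDraft,
                          key_set: frozenset[str]) -> None:
        policy = self._uniqueness.get(type_name, "none")
        if callable(policy):
            policy(self, type_name, draft)
            return
        ct = self.store.compound_types[type_name]
        if policy == "by_cas" and draft.cas is not None:
            row = conn.execute(
                f"SELECT id FROM {ct.table} WHERE cas = ? AND id IS NOT ?",
                (draft.cas, draft.id)).fetchone()
            if row:
                raise UniquenessError(
                    f"compound with cas {draft.cas!r} exists (id {row[0]})")
        elif policy == "by_exact_composition":
            for cid, in conn.execute(
                    f"SELECT DISTINCT compound_id FROM "
                    f"{ct.composition_table} c JOIN structures s "
                    f"ON s.id = c.structure_id WHERE s.structure_key IN "
                    f"({', '.join('?' * len(key_set))})",
                    tuple(key_set)).fetchall():
                if cid == draft.id:
                    continue
                keys = frozenset(r[0] for r in conn.execute(
                    f"SELECT s.structure_key FROM {ct.composition_table} c "
                    f"JOIN structures s ON s.id = c.structure_id "
                    f"WHERE c.compound_id = ?", (cid,)))
                if keys == key_set:
                    raise UniquenessError(
                        f"compound {cid} has the same composition")

    # -- compounds ---------------------------------------------------------

    def save_compound(self, type_name: str, draft: CompoundDraft,
                      actor: str) -> SaveOutcome:
        guard_write(self.security, "save", type_name)
        ct = self.store.compound_types[type_name]
        with self.store.transaction() as conn:
            draft = self._run_hook(type_name, draft)
            expanded = self._expand_compositions(draft)
            key_set = frozenset(structure_key(m).key for m, _ in expanded)
            self._check_uniqueness(conn, type_name, draft, key_set)
            created = reused = 0
            memberships: dict[int, float | None] = {}
            seen: dict[str, int] = {}
            for mol, pct in expanded:
                key = structure_key(mol).key
                if key in seen:
                    sid = seen[key]
                else:
                    sid, was_new = self._resolve_structure(conn, mol, actor)
                    seen[key] = sid
                    created += was_new
                    reused += not was_new
                if sid in memberships:
                    old = memberships[sid]
                    memberships[sid] = (old + pct if old is not None
                                        and pct is not None else None)
                else:
                    memberships[sid] = pct
            now = _now()
            extra_cols = [n for n, _ in ct.extra_columns
                          if n in draft.extra]
            cols = ("compound_name, cas, read_role, created_by, created_at,"
                    " modified_by, modified_at, version")
            vals = [draft.compound_name, draft.cas, draft.read_role,
                    actor, now, actor, now, 0]
            if extra_cols:
                cols += ", " + ", ".join(extra_cols)
                vals += [draft.extra[n] for n in extra_cols]
            try:
                cur = conn.execute(
                    f"INSERT INTO {ct.table} ({cols}) VALUES "
                    f"({', '.join('?' * len(vals))})", vals)
                cid = cur.lastrowid
                for sid, pct in memberships.items():
                    conn.execute(
                        f"INSERT INTO {ct.composition_table} "
                        f"(compound_id, structure_id, percentage) "
                        f"VALUES (?, ?, ?)", (cid, sid, pct))
            except sqlite3.IntegrityError as exc:
                raise ConstraintError(str(exc)) from exc
            self._invalidate(conn, type_name)
        return SaveOutcome(self.get_compound(type_name, cid),
                           structures_created=created,
                           structures_reused=reused)

    def update_compound(self, type_name: str, draft: CompoundDraft,
                        actor: str) -> SaveOutcome:
        guard_write(self.security, "update", type_name)
        if draft.id is None:
            raise NotFoundError("update requires draft.id")
        ct = self.store.compound_types[type_name]
        with self.store.transaction() as conn:
            draft = self._run_hook(type_name, draft)
            row = conn.execute(
                f"SELECT version FROM {ct.table} WHERE id = ?",
                (draft.id,)).fetchone()
            if row is None:
                raise NotFoundError(f"compound {draft.id} not found")
            if draft.expected_version is None:
                raise ConcurrentModificationError(
                    "update requires expected_version")
            expanded = self._expand_compositions(draft)
            key_set = frozenset(structure_key(m).key for m, _ in expanded)
            self._check_uniqueness(conn, type_name, draft, key_set)
            created = reused = 0
            memberships: dict[int, float | None] = {}
            seen: dict[str, int] = {}
            for mol, pct in expanded:
                key = structure_key(mol).key
                if key in seen:
                    sid = seen[key]
                else:
                    sid, was_new = self._resolve_structure(conn, mol, actor)
                    seen[key] = sid
                    created += was_new
                    reused += not was_new
                memberships.setdefault(sid, pct)
            sets = ("compound_name = ?, cas = ?, read_role = ?, "
                    "modified_by = ?, modified_at = ?, "
                    "version = version + 1")
            vals = [draft.compound_name, draft.cas, draft.read_role,
                    actor, _now()]
            extra_cols = [n for n, _ in ct.extra_columns
                          if n in draft.extra]
            for n in extra_cols:
                sets += f", {n} = ?"
                vals.append(draft.extra[n])
            vals += [draft.id, draft.expected_version]
            cur = conn.execute(
                f"UPDATE {ct.table} SET {sets} WHERE id = ? AND "
                f"version = ?", vals)
            if cur.rowcount == 0:
                raise ConcurrentModificationError(
                    f"compound {draft.id}: expected version "
                    f"{draft.expected_version}, found {row['version']}")
            conn.execute(
                f"DELETE FROM {ct.composition_table} WHERE compound_id = ?",
                (draft.id,))
            for sid, pct in memberships.items():
                conn.execute(
                    f"INSERT INTO {ct.composition_table} "
                    f"(compound_id, structure_id, percentage) "
                    f"VALUES (?, ?, ?)", (draft.id, sid, pct))
            self._invalidate(conn, type_name)
        return SaveOutcome(self.get_compound(type_name, draft.id),
                           structures_created=created,
                           structures_reused=reused)

    def delete_compound(self, type_name: str, compound_id: int,
                        actor: str) -> None:
        guard_write(self.security, "delete", type_name)
        ct = self.store.compound_types[type_name]
        with self.store.transaction() as conn:
            cur = conn.execute(f"DELETE FROM {ct.table} WHERE id = ?",
                               (compound_id,))
            if cur.rowcount == 0:
                raise NotFoundError(f"compound {compound_id} not found")
            self._invalidate(conn, type_name)

    def get_compound(self, type_name: str, compound_id: int) -> dict:
        ct = self.store.compound_types[type_name]
        row = self.store.conn.execute(
            f"SELECT * FROM {ct.table} WHERE id = ?",
            (compound_id,)).fetchone()
        if row is None:
            raise NotFoundError(f"compound {compound_id} not found")
        record = dict(row)
        record["type"] = type_name
        record["compositions"] = [
            dict(r) for r in self.store.conn.execute(
                f"SELECT c.structure_id, c.percentage, s.structure_text, "
                f"s.structure_key, s.mol_weight FROM {ct.composition_table} "
                f"c JOIN structures s ON s.id = c.structure_id "
                f"WHERE c.compound_id = ? ORDER BY c.id", (compound_id,))]
        return record

    # -- structures --------------------------------------------------------

    def replace_structure(self, key: str, new_structure_text: str,
                          actor: str) -> int:
        """Repoint every composition referencing the structure with ``key``
        to the structure of ``new_structure_text`` (existing row or a new
        one). The old row remains unchanged. Returns the number of
        affected compositions."""
        guard_write(self.security, "update", "structure")
        with self.store.transaction() as conn:
            row = conn.execute(
                "SELECT id FROM structures WHERE structure_key = ?",
                (key,)).fetchone()
            if row is None:
                raise NotFoundError(f"no structure with key {key!r}")
            old_id = row[0]
            mol = parse_structure(new_structure_text)
            parts = split_components(mol)
            if len(parts) != 1:
                raise ParseError(
                    "replacement structure must be a single component")
            new_id, _ = self._resolve_structure(conn, parts[0], actor)
            affected = 0
            for ct in self.store.compound_types.values():
                n = conn.execute(
                    f"SELECT COUNT(*) FROM {ct.composition_table} "
                    f"WHERE structure_id = ?", (old_id,)).fetchone()[0]
                affected += n
                # merge memberships if a compound already holds the new
                # structure, then repoint the rest
                conn.execute(
                    f"UPDATE OR IGNORE {ct.composition_table} "
                    f"SET structure_id = ? WHERE structure_id = ?",
                    (new_id, old_id))
                conn.execute(
                    f"DELETE FROM {ct.composition_table} "
                    f"WHERE structure_id = ?", (old_id,))
            self._invalidate(conn, "structure")
        return affected

    # -- containables / containers -----------------------------------------

    def save_containable(self, type_name: str, draft: ContainableDraft,
                         actor: str) -> SaveOutcome:
        guard_write(self.security, "save", type_name)
        nt = self.store.containable_types[type_name]
        parent = self.store.compound_types[nt.compound_type]
        with self.store.transaction() as conn:
            draft = self._run_hook(type_name, draft)
            if conn.execute(f"SELECT 1 FROM {parent.table} WHERE id = ?",
                            (draft.compound_id,)).fetchone() is None:
                raise NotFoundError(
                    f"compound {draft.compound_id} not found")
            now = _now()
            extra_cols = [n for n, _ in nt.extra_columns
                          if n in draft.extra]
            cols = ("compound_id, read_role, created_by, created_at, "
                    "modified_by, modified_at, version")
            vals = [draft.compound_id, draft.read_role, actor, now, actor,
                    now, 0]
            if extra_cols:
                cols += ", " + ", ".join(extra_cols)
                vals += [draft.extra[n] for n in extra_cols]
            cur = conn.execute(
                f"INSERT INTO {nt.table} ({cols}) VALUES "
                f"({', '.join('?' * len(vals))})", vals)
            self._invalidate(conn, type_name)
            record = dict(conn.execute(
                f"SELECT * FROM {nt.table} WHERE id = ?",
                (cur.lastrowid,)).fetchone())
        record["type"] = type_name
        return SaveOutcome(record, 0, 0)

    def save_container(self, draft: ContainerDraft, actor: str) -> dict:
        guard_write(self.security, "save", "container")
        if draft.barcode is None:
            raise ConstraintError("container barcode must not be null")
        nt = self.store.containable_types.get(draft.containable_type)
        if nt is None:
            raise NotFoundError(
                f"unknown containable type {draft.containable_type!r}")
        with self.store.transaction() as conn:
            if conn.execute(f"SELECT 1 FROM {nt.table} WHERE id = ?",
                            (draft.containable_id,)).fetchone() is None:
                raise NotFoundError(
                    f"containable {draft.containable_id} not found")
            now = _now()
            try:
                cur = conn.execute(
                    "INSERT INTO containers (barcode, containable_type, "
                    "containable_id, created_by, created_at, modified_by, "
                    "modified_at, version) VALUES (?, ?, ?, ?, ?, ?, ?, 0)",
                    (draft.barcode, draft.containable_type,
                     draft.containable_id, actor, now, actor, now))
            except sqlite3.IntegrityError as exc:
                if "UNIQUE" in str(exc):
                    raise UniquenessError(
                        f"barcode {draft.barcode!r} already used") from exc
                raise ConstraintError(str(exc)) from exc
            self._invalidate(conn, "container")
            record = dict(conn.execute(
                "SELECT * FROM containers WHERE id = ?",
                (cur.lastrowid,)).fetchone())
        return record

    # -- cache invalidation -------------------------------------------------

    def _invalidate(self, conn, entity_kind: str) -> None:
        """Clear count-cache entries made stale by a write. Structure and
        compound/containable writes reach every searchable kind through the
        composition graph, so they clear the whole cache; container writes
        only affect container queries."""
        if entity_kind == "container":
            conn.execute("DELETE FROM search_count_cache "
                         "WHERE entity_kind = 'container'")
        else:
            conn.execute("DELETE FROM search_count_cache")
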