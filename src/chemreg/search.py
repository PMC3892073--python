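"""Combined structure + property search with paging and cached counts.

Semantics
---------
A compound matches when **at least one** of its component structures
satisfies the structure query (and its molecular-weight bounds), and the
compound row satisfies every property filter and — when security is
enabled — the read-role predicate. Without ``distinct``, the result has
one row per *matching component* (a mixture whose two components both
match contributes two rows); with ``distinct``, each compound appears at
most once. Results are fully sorted (requested keys, then id ascending as
a deterministic tie-break) before the requested page is sliced.

Counting
--------
Paging needs the total hit count; recomputing it for every page is the
dominant cost of paged queries, so the count is computed on the first
execution of a logical query (the request minus paging and sort, plus the
user's role set) and cached in the store. Writes invalidate the cache
(see :meth:`chemreg.registry.Registry._invalidate`).

Planning
--------
With both a structure query and property filters, the engine chooses
between two equivalent strategies: ``INDEX_SCREEN`` (fingerprint screen
over all stored structures, verify survivors, then apply filters) and
``PROPERTY_FIRST`` (fetch the compounds selected by the property filters,
then verify only their components). ``PROPERTY_FIRST`` wins when the
estimated filter selectivity is small; the estimate comes from
:meth:`chemreg.store.Store.table_stats` (distinct-value counts for
equality, value-sample prefix hits for ``like-prefix``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

from .chem import (canonical_form, element_counts, parse_formula,
                   parse_structure, split_components, structure_key)
from .errors import ParseError, UnknownFieldError
from .matching import (Fingerprint, fingerprint, match_smarts,
                       match_substructure, similarity)
from .registry import Registry
from .security import SecurityContext, readable_predicate

__all__ = ["StructureQuery", "SearchRequest", "Page", "PlanDecision",
           "SearchService"]

logger = logging.getLogger("chemreg.search")

_OPS = ("eq", "like-prefix", "range")


@dataclass
class StructureQuery:
    mode: str                      # exact | sub | smarts | similarity | formula
    query_text: str
    metric: str = "tanimoto"
    alpha: float = 1.0
    beta: float = 1.0
    min_score: float = 0.0
    max_score: float = 1.0
    mw_min: float | None = None
    mw_max: float | None = None

    def __post_init__(self):
        if self.mode not in ("exact", "sub", "smarts", "similarity",
                             "formula"):
            raise ValueError(f"unknown structure search mode {self.mode!r}")
        if self.min_score > self.max_score:
            raise ValueError("min_score > max_score")
        if (self.mw_min is not None and self.mw_max is not None
                and self.mw_min > self.mw_max):
            raise ValueError("mw_min > mw_max")


@dataclass
class SearchRequest:
    target: str                    # compound/containable type or "container"
    structure: StructureQuery | None = None
    filters: list[tuple[str, str, object]] = field(default_factory=list)
    sort: list[tuple[str, str]] = field(default_factory=list)
    page_index: int = 0
    page_size: int = 4
    distinct: bool | None = None   # None -> service default

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SearchRequest":
        d = dict(d)
        if d.get("structure"):
            d["structure"] = StructureQuery(**d["structure"])
        d["filters"] = [tuple(f) for f in d.get("filters", [])]
        d["sort"] = [tuple(s) for s in d.get("sort", [])]
        return cls(**d)


@dataclass
class Page:
    items: list[dict]
    page_index: int
    page_size: int
    total_count: int
    count_from_cache: bool


@dataclass
class PlanDecision:
    strategy: str                  # INDEX_SCREEN | PROPERTY_FIRST
    estimated_candidates: int


class SearchService:
    """Search over a :class:`~chemreg.registry.Registry`'s store."""

    def __init__(self, registry: Registry, tau: float = 0.05,
                 n_max: int = 5000, distinct_default: bool = True,
                 page_size_default: int = 4):
        self.registry = registry
        self.store = registry.store
        self.tau = tau
        self.n_max = n_max
        self.distinct_default = distinct_default
        self.page_size_default = page_size_default
        # instrumentation (reset freely in tests)
        self.count_computations = 0
        self.verifications = 0
        self.last_plan: PlanDecision | None = None

    def set_distinct_default(self, enabled: bool) -> None:
        """Default for requests that leave ``distinct`` unset. Disabling is
        safe for single-component compound stores, where distinct and
        non-distinct results coincide."""
        self.distinct_default = enabled

    # -- request plumbing --------------------------------------------------

    def _columns(self, table: str) -> list[str]:
        return [r[1] for r in
                self.store.conn.execute(f"PRAGMA table_info({table})")]

    def _context(self, user: str | None) -> SecurityContext:
        base = self.registry.security
        if not base.enabled:
            return base
        roles = base.roles if user is None else self.registry.user_roles(user)
        return SecurityContext(enabled=True, user=user or base.user,
                               roles=frozenset(roles),
                               permissions=base.permissions)

    def _filter_sql(self, table_alias: str, columns: list[str],
                    filters) -> tuple[list[str], list]:
        conds, params = [], []
        for fld, op, value in filters:
            if fld not in columns:
                raise UnknownFieldError(
                    f"{fld!r} is not a column of the search target")
            col = f"{table_alias}.{fld}"
            if op == "eq":
                conds.append(f"{col} = ?")
                params.append(value)
            elif op == "like-prefix":
                escaped = (str(value).replace("\\", "\\\\")
                           .replace("%", "\\%").replace("_", "\\_"))
                conds.append(f"{col} LIKE ? ESCAPE '\\'")
                params.append(escaped + "%")
            elif op == "range":
                lo, hi = value
                if lo is not None:
                    conds.append(f"{col} >= ?")
                    params.append(lo)
                if hi is not None:
                    conds.append(f"{col} <= ?")
                    params.append(hi)
            else:
                raise UnknownFieldError(f"unknown filter operator {op!r}")
        return conds, params

    # -- planner -----------------------------------------------------------

    def plan(self, request: SearchRequest, stats: dict) -> PlanDecision:
        """Choose the evaluation strategy for a structure query."""
        if request.structure is None:
            raise ValueError("plan() requires a structure query")
        if request.target == "container":
            table = "containers"
        else:
            ct = self.store.compound_types.get(request.target)
            table = ct.table if ct else \
                self.store.containable_types[request.target].table
        tstats = stats.get(table, {"rows": 0, "columns": {}})
        rows = tstats["rows"]
        if not request.filters or rows == 0:
            decision = PlanDecision("INDEX_SCREEN",
                                    stats.get("structures",
                                              {"rows": 0})["rows"])
            self._log_plan(decision)
            return decision
        est = rows
        for fld, op, value in request.filters:
            cstats = tstats["columns"].get(fld)
            if cstats is None:
                continue
            if op == "eq":
                distinct = max(1, cstats["distinct"])
                est = min(est, rows / distinct)
            elif op == "like-prefix":
                sample = cstats["sample"]
                if sample:
                    frac = sum(1 for v in sample
                               if str(v).startswith(str(value))) / len(sample)
                    # sampled zero hits still means "rare", not impossible
                    frac = max(frac, 1.0 / (2 * len(sample)))
                    est = min(est, rows * frac)
            elif op == "range":
                est = min(est, rows * 0.25)
        est = int(round(est))
        if est <= self.tau * rows and est <= self.n_max:
            decision = PlanDecision("PROPERTY_FIRST", est)
        else:
            decision = PlanDecision("INDEX_SCREEN", est)
        self._log_plan(decision)
        return decision

    def _log_plan(self, decision: PlanDecision) -> None:
        self.last_plan = decision
        logger.debug("plan decision strategy=%s estimated_candidates=%d",
                     decision.strategy, decision.estimated_candidates)

    # -- structure verification --------------------------------------------

    def _make_verifier(self, sq: StructureQuery):
        """Return (prefilter_sql, verify) where ``verify(row) -> bool``
        decides whether one structure row satisfies the query. ``row``
        needs structure_text, structure_key, mol_weight, fp_bits,
        fp_popcount, fp_params columns."""
        params = self.registry.fp_params
        mode = sq.mode
        if mode == "exact":
            qmol = parse_structure(sq.query_text)
            parts = split_components(qmol)
            if len(parts) != 1:
                raise ParseError("exact search expects a single component")
            qkey = structure_key(parts[0]).key

            def verify(row):
                return row["structure_key"] == qkey
        elif mode == "sub":
            qmol = parse_structure(sq.query_text)
            qfp = fingerprint(qmol, params)

            def verify(row):
                fp = Fingerprint.from_bytes(row["fp_bits"], params.n_bits,
                                            row["fp_params"])
                if not qfp.is_subset_of(fp):
                    return False
                self.verifications += 1
                target = parse_structure(row["structure_text"])
                return match_substructure(target, qmol).matched
        elif mode == "smarts":
            pattern = parse_structure(sq.query_text, format="smarts")

            def verify(row):
                self.verifications += 1
                target = parse_structure(row["structure_text"])
                return match_smarts(target, pattern)
        elif mode == "similarity":
            qmol = parse_structure(sq.query_text)
            qfp = fingerprint(qmol, params)

            def verify(row):
                fp = Fingerprint.from_bytes(row["fp_bits"], params.n_bits,
                                            row["fp_params"])
                score = similarity(qfp, fp, sq.metric, sq.alpha, sq.beta)
                return sq.min_score <= score <= sq.max_score
        elif mode == "formula":
            counts = parse_formula(sq.query_text)

            def verify(row):
                target = parse_structure(row["structure_text"])
                return element_counts(target) == counts
        else:  # pragma: no cover - guarded by StructureQuery
            raise ValueError(mode)

        def verify_with_mw(row):
            if sq.mw_min is not None and row["mol_weight"] < sq.mw_min:
                return False
            if sq.mw_max is not None and row["mol_weight"] > sq.mw_max:
                return False
            return verify(row)

        return verify_with_mw

    def _screen_structure_ids(self, sq: StructureQuery) -> set[int]:
        """INDEX_SCREEN path: structure ids satisfying the query, found by
        scanning the structure table (fingerprint screen + verification)."""
        verify = self._make_verifier(sq)
        sql = ("SELECT id, structure_text, structure_key, mol_weight, "
               "fp_bits, fp_popcount, fp_params FROM structures")
        conds, params = [], []
        if sq.mw_min is not None:
            conds.append("mol_weight >= ?")
            params.append(sq.mw_min)
        if sq.mw_max is not None:
            conds.append("mol_weight <= ?")
            params.append(sq.mw_max)
        if sq.mode == "exact":
            qmol = parse_structure(sq.query_text)
            parts = split_components(qmol)
            conds.append("structure_key = ?")
            params.append(structure_key(parts[0]).key)
        if conds:
            sql += " WHERE " + " AND ".join(conds)
        return {row["id"] for row in self.store.conn.execute(sql, params)
                if verify(row)}

    # -- core search -------------------------------------------------------

    def _matched_rows(self, request: SearchRequest, ctx: SecurityContext
                      ) -> list[dict]:
        """All matching rows, unsorted, one per (entity, matching
        component) — or one per entity when there is no structure query."""
        if request.target == "container":
            return self._matched_container_rows(request, ctx)
        ct = self.store.compound_types.get(request.target)
        if ct is None:
            nt = self.store.containable_types.get(request.target)
            if nt is None:
                raise UnknownFieldError(
                    f"unknown search target {request.target!r}")
            return self._matched_containable_rows(request, nt, ctx)
        columns = self._columns(ct.table)
        conds, params = self._filter_sql("k", columns, request.filters)
        pred, pparams = readable_predicate(ctx, "k.read_role")
        conds.append(pred)
        params.extend(pparams)
        where = " AND ".join(conds)

        if request.structure is None:
            sql = f"SELECT k.* FROM {ct.table} k WHERE {where}"
            return [dict(r) | {"matched_structure_id": None}
                    for r in self.store.conn.execute(sql, params)]

        strategy = self.plan(request, self.store.table_stats()).strategy \
            if request.filters else self._trivial_plan()
        if strategy == "PROPERTY_FIRST":
            verify = self._make_verifier(request.structure)
            sql = (f"SELECT k.*, c.structure_id AS matched_structure_id, "
                   f"s.structure_text, s.structure_key, s.mol_weight, "
                   f"s.fp_bits, s.fp_popcount, s.fp_params "
                   f"FROM {ct.table} k "
                   f"JOIN {ct.composition_table} c ON c.compound_id = k.id "
                   f"JOIN structures s ON s.id = c.structure_id "
                   f"WHERE {where} ORDER BY k.id, c.structure_id")
            out = []
            verdicts: dict[int, bool] = {}
            for row in self.store.conn.execute(sql, params):
                sid = row["matched_structure_id"]
                if sid not in verdicts:
                    verdicts[sid] = verify(row)
                if verdicts[sid]:
                    out.append(self._project(row, columns))
            return out
        sids = self._screen_structure_ids(request.structure)
        if not sids:
            return []
        marks = ", ".join("?" * len(sids))
        sql = (f"SELECT k.*, c.structure_id AS matched_structure_id "
               f"FROM {ct.table} k "
               f"JOIN {ct.composition_table} c ON c.compound_id = k.id "
               f"WHERE c.structure_id IN ({marks}) AND {where}")
        return [dict(r) for r in
                self.store.conn.execute(sql, list(sids) + params)]

    def _trivial_plan(self) -> str:
        decision = PlanDecision(
            "INDEX_SCREEN",
            self.store.conn.execute(
                "SELECT COUNT(*) FROM structures").fetchone()[0])
        self._log_plan(decision)
        return decision.strategy

    @staticmethod
    def _project(row, columns) -> dict:
        d = {c: row[c] for c in columns}
        d["matched_structure_id"] = row["matched_structure_id"]
        return d

    def _matched_containable_rows(self, request, nt, ctx) -> list[dict]:
        parent = self.store.compound_types[nt.compound_type]
        columns = self._columns(nt.table)
        conds, params = self._filter_sql("n", columns, request.filters)
        for col, pp in (("n.read_role", None), ("k.read_role", None)):
            pred, pparams = readable_predicate(ctx, col)
            conds.append(pred)
            params.extend(pparams)
        where = " AND ".join(conds)
        if request.structure is None:
            sql = (f"SELECT n.* FROM {nt.table} n "
                   f"JOIN {parent.table} k ON k.id = n.compound_id "
                   f"WHERE {where}")
            return [dict(r) | {"matched_structure_id": None}
                    for r in self.store.conn.execute(sql, params)]
        sids = self._screen_structure_ids(request.structure)
        if not sids:
            return []
        marks = ", ".join("?" * len(sids))
        sql = (f"SELECT n.*, c.structure_id AS matched_structure_id "
               f"FROM {nt.table} n "
               f"JOIN {parent.table} k ON k.id = n.compound_id "
               f"JOIN {parent.composition_table} c ON c.compound_id = k.id "
               f"WHERE c.structure_id IN ({marks}) AND {where}")
        return [dict(r) for r in
                self.store.conn.execute(sql, list(sids) + params)]

    def _matched_container_rows(self, request, ctx) -> list[dict]:
        columns = self._columns("containers")
        conds, params = self._filter_sql("t", columns, request.filters)
        sids = None
        if request.structure is not None:
            sids = self._screen_structure_ids(request.structure)
            if not sids:
                return []
        out: list[dict] = []
        for nt in self.store.containable_types.values():
            parent = self.store.compound_types[nt.compound_type]
            tconds = list(conds)
            tparams = list(params)
            tconds.append("t.containable_type = ?")
            tparams.append(nt.name)
            for col in ("n.read_role", "k.read_role"):
                pred, pparams = readable_predicate(ctx, col)
                tconds.append(pred)
                tparams.extend(pparams)
            where = " AND ".join(tconds)
            if sids is None:
                sql = (f"SELECT t.* FROM containers t "
                       f"JOIN {nt.table} n ON n.id = t.containable_id "
                       f"JOIN {parent.table} k ON k.id = n.compound_id "
                       f"WHERE {where}")
                out.extend(dict(r) | {"matched_structure_id": None}
                           for r in self.store.conn.execute(sql, tparams))
            else:
                marks = ", ".join("?" * len(sids))
                sql = (f"SELECT t.*, c.structure_id AS matched_structure_id "
                       f"FROM containers t "
                       f"JOIN {nt.table} n ON n.id = t.containable_id "
                       f"JOIN {parent.table} k ON k.id = n.compound_id "
                       f"JOIN {parent.composition_table} c "
                       f"ON c.compound_id = k.id "
                       f"WHERE c.structure_id IN ({marks}) AND {where}")
                out.extend(dict(r) for r in
                           self.store.conn.execute(sql,
                                                   list(sids) + tparams))
        return out

    # -- sorting / distinct / paging ---------------------------------------

    @staticmethod
    def _sort_rows(rows: list[dict], sort: list[tuple[str, str]]
                   ) -> list[dict]:
        # deterministic tie-break: id ascending, then matching component
        rows.sort(key=lambda r: (r["id"], r.get("matched_structure_id")
                                 or 0))
        for fld, direction in reversed(sort):
            if rows and fld not in rows[0]:
                raise UnknownFieldError(f"cannot sort by {fld!r}")
            rows.sort(key=lambda r: (r[fld] is None, r[fld]),
                      reverse=(direction == "desc"))
        return rows

    @staticmethod
    def _distinct_rows(rows: list[dict]) -> list[dict]:
        seen: set[int] = set()
        out = []
        for r in rows:
            if r["id"] not in seen:
                seen.add(r["id"])
                out.append(r)
        return out

    def _cache_key(self, request: SearchRequest, ctx: SecurityContext,
                   distinct: bool) -> str:
        sq = request.structure
        sq_part = None
        if sq is not None:
            if sq.mode in ("exact", "sub", "similarity"):
                qnorm = canonical_form(parse_structure(sq.query_text))
            else:
                qnorm = sq.query_text.strip()
            sq_part = [sq.mode, qnorm, sq.metric, sq.alpha, sq.beta,
                       sq.min_score, sq.max_score, sq.mw_min, sq.mw_max]
        payload = {
            "target": request.target,
            "structure": sq_part,
            "filters": sorted([list(map(str, (f, o))) + [repr(v)]
                               for f, o, v in request.filters]),
            "distinct": distinct,
            "security": sorted(ctx.roles) if ctx.enabled else None,
        }
        return json.dumps(payload, sort_keys=True)

    def _entity_kind(self, target: str) -> str:
        return target if target == "container" else (
            target if target in self.store.compound_types
            else target)

    # -- public API --------------------------------------------------------

    def search(self, request: SearchRequest, user: str | None = None
               ) -> Page:
        ctx = self._context(user)
        distinct = (self.distinct_default if request.distinct is None
                    else request.distinct)
        rows = self._matched_rows(request, ctx)
        rows = self._sort_rows(rows, request.sort)
        if distinct:
            rows = self._distinct_rows(rows)
        total = len(rows)
        key = self._cache_key(request, ctx, distinct)
        cached = self.store.conn.execute(
            "SELECT total_count FROM search_count_cache WHERE cache_key = ?",
            (key,)).fetchone()
        if cached is None:
            self.count_computations += 1
            logger.debug("count computed: %d hits", total)
            with self.store.transaction() as conn:
                conn.execute(
                    "INSERT OR REPLACE INTO search_count_cache "
                    "(cache_key, entity_kind, total_count) VALUES (?, ?, ?)",
                    (key, self._entity_kind(request.target), total))
            from_cache = False
        else:
            from_cache = True
            total = cached[0]
        size = request.page_size or self.page_size_default
        start = request.page_index * size
        return Page(items=rows[start:start + size],
                    page_index=request.page_index, page_size=size,
                    total_count=total, count_from_cache=from_cache)

    def count(self, request: SearchRequest, user: str | None = None
              ) -> tuple[int, bool]:
        """Total hit count and whether it came from the cache."""
        ctx = self._context(user)
        distinct = (self.distinct_default if request.distinct is None
                    else request.distinct)
        key = self._cache_key(request, ctx, distinct)
        cached = self.store.conn.execute(
            "SELECT total_count FROM search_count_cache WHERE cache_key = ?",
            (key,)).fetchone()
        if cached is not None:
            return cached[0], True
        rows = self._matched_rows(request, ctx)
        if distinct:
            rows = self._distinct_rows(rows)
        total = len(rows)
        self.count_computations += 1
        logger.debug("count computed: %d hits", total)
        with self.store.transaction() as conn:
            conn.execute(
                "INSERT OR REPLACE INTO search_count_cache "
                "(cache_key, entity_kind, total_count) VALUES (?, ?, ?)",
                (key, self._entity_kind(request.target), total))
        return total, False

    def find_by_cas(self, type_name: str, cas: str) -> list[dict]:
        """All compounds of a type with exactly this (non-unique) CAS."""
        ct = self.store.compound_types[type_name]
        return [dict(r) for r in self.store.conn.execute(
            f"SELECT * FROM {ct.table} WHERE cas = ? ORDER BY id", (cas,))]

    def search_containers(self, request: SearchRequest,
                          user: str | None = None) -> Page:
        request.target = "container"
        return self.search(request, user)
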