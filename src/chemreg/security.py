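"""Optional role-based read filtering and method-level write guards.

Reads: every searchable entity may carry a ``read_role``; when security is
enabled, a predicate ``read_role IS NULL OR read_role IN (user's roles)``
is conjoined into the query's WHERE clause (never applied as a post-filter,
so paging and counts stay consistent). A null ``read_role`` means
world-readable.

Writes: a role→operation permission map from the configuration; when
security is enabled and no permission is configured for an entity kind the
write is denied (deny-by-default). Authentication is out of scope — the
caller constructs the :class:`SecurityContext`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import AuthorizationError

__all__ = ["SecurityContext", "readable_predicate", "guard_write"]


@dataclass(frozen=True)
class SecurityContext:
    enabled: bool = False
    user: str | None = None
    roles: frozenset[str] = frozenset()
    # permissions: entity kind -> operation -> set of roles allowed
    permissions: dict = field(default_factory=dict)

    @classmethod
    def disabled(cls) -> "SecurityContext":
        return cls(enabled=False)


def readable_predicate(context: SecurityContext, column: str = "read_role"
                       ) -> tuple[str, list]:
    """SQL predicate fragment + parameters restricting ``column`` to roles
    the context may read. Permissive (``1=1``) when security is disabled."""
    if not context.enabled:
        return "1=1", []
    roles = sorted(context.roles)
    if not roles:
        return f"{column} IS NULL", []
    marks = ", ".join("?" for _ in roles)
    return f"({column} IS NULL OR {column} IN ({marks}))", list(roles)


def guard_write(context: SecurityContext, operation: str, entity_kind: str
                ) -> None:
    """Raise :class:`AuthorizationError` unless the context may perform
    ``operation`` on ``entity_kind``. Always allows when disabled."""
    if not context.enabled:
        return
    kind_map = context.permissions.get(entity_kind)
    if not kind_map:
        raise AuthorizationError(
            f"no write permissions configured for {entity_kind!r}")
    allowed = set(kind_map.get(operation, ())) | set(kind_map.get("*", ()))
    if not (set(context.roles) & allowed):
        raise AuthorizationError(
            f"user {context.user!r} may not {operation} {entity_kind!r}")
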