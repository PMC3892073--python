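"""High-level facade wiring store, registry, search and security together.

Typical use::

    from chemreg import CompoundDatabase, CompoundDraft

    db = CompoundDatabase(":memory:")
    db.init()
    db.save_compound(CompoundDraft(compositions=[("CCO", None)],
                                   compound_name="ethanol"), actor="alice")
    page = db.search_sub("c1ccccc1")

``CompoundDatabase`` registers a default compound type ``compound`` with
paired containable type ``batch``; applications with several concrete
compound classes register more before :meth:`init`.
"""

from __future__ import annotations

from .config import AppConfig
from .registry import (CompoundDraft, ContainableDraft, ContainerDraft,
                       Registry, SaveOutcome)
from .search import Page, SearchRequest, SearchService, StructureQuery
from .security import SecurityContext
from .store import Store

__all__ = ["CompoundDatabase"]


class CompoundDatabase:
    def __init__(self, path: str = ":memory:",
                 config: AppConfig | None = None,
                 register_defaults: bool = True):
        self.config = config or AppConfig()
        self.store = Store(path)
        if register_defaults:
            self.store.register_compound_type("compound")
            self.store.register_containable_type("batch", "compound")
        security = SecurityContext(
            enabled=self.config.security.enabled,
            permissions=self.config.security.permissions)
        self.registry = Registry(
            self.store, security=security,
            fp_params=self.config.fingerprint,
            store_canonical=self.config.store_canonical_smiles)
        self.search_service = SearchService(
            self.registry, tau=self.config.planner_tau,
            n_max=self.config.planner_n_max,
            distinct_default=self.config.distinct_default,
            page_size_default=self.config.page_size_default)

    # -- lifecycle ---------------------------------------------------------

    def register_compound_type(self, name, extra_columns=None):
        return self.store.register_compound_type(name, extra_columns)

    def register_containable_type(self, name, compound_type,
                                  extra_columns=None):
        return self.store.register_containable_type(name, compound_type,
                                                    extra_columns)

    def init(self) -> "CompoundDatabase":
        self.store.init_schema()
        return self

    def close(self) -> None:
        self.store.close()

    # -- security ----------------------------------------------------------

    def enable_security(self, permissions: dict | None = None,
                        user: str | None = None,
                        roles: frozenset[str] | None = None) -> None:
        self.registry.security = SecurityContext(
            enabled=True, user=user, roles=frozenset(roles or ()),
            permissions=permissions
            if permissions is not None
            else self.config.security.permissions)

    def disable_security(self) -> None:
        self.registry.security = SecurityContext.disabled()

    # -- registry delegation -----------------------------------------------

    def save_compound(self, draft: CompoundDraft, actor: str,
                      type_name: str = "compound") -> SaveOutcome:
        return self.registry.save_compound(type_name, draft, actor)

    def update_compound(self, draft: CompoundDraft, actor: str,
                        type_name: str = "compound") -> SaveOutcome:
        return self.registry.update_compound(type_name, draft, actor)

    def delete_compound(self, compound_id: int, actor: str,
                        type_name: str = "compound") -> None:
        self.registry.delete_compound(type_name, compound_id, actor)

    def get_compound(self, compound_id: int,
                     type_name: str = "compound") -> dict:
        return self.registry.get_compound(type_name, compound_id)

    def save_containable(self, draft: ContainableDraft, actor: str,
                         type_name: str = "batch") -> SaveOutcome:
        return self.registry.save_containable(type_name, draft, actor)

    def save_container(self, draft: ContainerDraft, actor: str) -> dict:
        return self.registry.save_container(draft, actor)

    def replace_structure(self, key: str, new_structure_text: str,
                          actor: str) -> int:
        return self.registry.replace_structure(key, new_structure_text,
                                               actor)

    def register_pre_save_hook(self, entity_kind, hook) -> None:
        self.registry.register_pre_save_hook(entity_kind, hook)

    def set_uniqueness_policy(self, policy, type_name: str = "compound"
                              ) -> None:
        self.registry.set_uniqueness_policy(type_name, policy)

    # -- search delegation ---------------------------------------------------

    def search(self, request: SearchRequest, user: str | None = None
               ) -> Page:
        return self.search_service.search(request, user)

    def count(self, request: SearchRequest, user: str | None = None):
        return self.search_service.count(request, user)

    def find_by_cas(self, cas: str, type_name: str = "compound"):
        return self.search_service.find_by_cas(type_name, cas)

    def set_distinct_default(self, enabled: bool) -> None:
        self.search_service.set_distinct_default(enabled)

    def stats(self) -> dict:
        return self.store.table_stats()

    # convenience one-liners used in examples and the CLI
    def search_sub(self, smiles: str, type_name: str = "compound",
                   **kwargs) -> Page:
        return self.search(SearchRequest(
            target=type_name,
            structure=StructureQuery(mode="sub", query_text=smiles),
            **kwargs))
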