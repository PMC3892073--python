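-- chemreg default schema (SQLite dialect)
-- generated from Store.ddl() for the default type registration:
-- compound type 'compound' paired with containable type 'batch'.
-- Registered extra columns append typed columns to the owning table.

CREATE TABLE IF NOT EXISTS structures (
    id INTEGER PRIMARY KEY,
    structure_text TEXT NOT NULL,
    structure_key TEXT NOT NULL UNIQUE,
    mol_weight REAL NOT NULL,
    fp_bits BLOB,
    fp_popcount INTEGER,
    fp_params TEXT,
    created_by TEXT NOT NULL,
    created_at TEXT NOT NULL,
    modified_by TEXT NOT NULL,
    modified_at TEXT NOT NULL,
    version INTEGER NOT NULL DEFAULT 0
);
CREATE INDEX IF NOT EXISTS ix_structures_mw ON structures (mol_weight);
CREATE TABLE IF NOT EXISTS roles (
    id INTEGER PRIMARY KEY,
    name TEXT NOT NULL UNIQUE
);
CREATE TABLE IF NOT EXISTS users (
    id INTEGER PRIMARY KEY,
    name TEXT NOT NULL UNIQUE
);
CREATE TABLE IF NOT EXISTS user_roles (
    user_name TEXT NOT NULL,
    role_name TEXT NOT NULL,
    UNIQUE (user_name, role_name)
);
CREATE TABLE IF NOT EXISTS search_count_cache (
    cache_key TEXT PRIMARY KEY,
    entity_kind TEXT NOT NULL,
    total_count INTEGER NOT NULL
);
CREATE TABLE IF NOT EXISTS compound_compound (
    id INTEGER PRIMARY KEY,
    compound_name TEXT,
    cas TEXT,
    read_role TEXT,
    created_by TEXT NOT NULL,
    created_at TEXT NOT NULL,
    modified_by TEXT NOT NULL,
    modified_at TEXT NOT NULL,
    version INTEGER NOT NULL DEFAULT 0
);
CREATE INDEX IF NOT EXISTS ix_compound_compound_cas ON compound_compound (cas);
CREATE INDEX IF NOT EXISTS ix_compound_compound_name ON compound_compound (compound_name);
CREATE TABLE IF NOT EXISTS composition_compound (
    id INTEGER PRIMARY KEY,
    compound_id INTEGER NOT NULL REFERENCES compound_compound (id)
        ON DELETE CASCADE,
    structure_id INTEGER NOT NULL REFERENCES structures (id),
    percentage REAL
        CHECK (percentage IS NULL
               OR (percentage > 0 AND percentage <= 100)),
    UNIQUE (compound_id, structure_id)
);
CREATE INDEX IF NOT EXISTS ix_composition_compound_sid ON composition_compound (structure_id);
CREATE TABLE IF NOT EXISTS containable_batch (
    id INTEGER PRIMARY KEY,
    compound_id INTEGER NOT NULL REFERENCES compound_compound (id),
    read_role TEXT,
    created_by TEXT NOT NULL,
    created_at TEXT NOT NULL,
    modified_by TEXT NOT NULL,
    modified_at TEXT NOT NULL,
    version INTEGER NOT NULL DEFAULT 0
);
CREATE TABLE IF NOT EXISTS containers (
    id INTEGER PRIMARY KEY,
    barcode TEXT NOT NULL UNIQUE,
    containable_type TEXT NOT NULL,
    containable_id INTEGER NOT NULL,
    created_by TEXT NOT NULL,
    created_at TEXT NOT NULL,
    modified_by TEXT NOT NULL,
    modified_at TEXT NOT NULL,
    version INTEGER NOT NULL DEFAULT 0
);
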