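# chemreg

An embeddable chemical compound registration database for Python:
structure-searchable storage of (possibly multi-component) compounds,
batches/lots and bar-coded containers, built for teams that need an
in-house registration or inventory store without running a database
cartridge. The library is the interface; a thin `chemreg` CLI covers
shell workflows (init, SD-file import/export, search, fixtures).

**Who it is for.** Research groups and informatics developers building
compound databases, registration systems or inventories where compounds
must be found by chemical structure *and* ordinary properties in one
query, results must be paged, and structure bookkeeping (deduplication,
immutability, mixtures, salts) must be handled by the store rather than
by every application.

## The model in brief

* **Structure identity and dedup.** Every stored structure is unique and
  immutable, keyed by its standard InChIKey under a database unique
  constraint. Saving a compound reuses existing structure rows by key;
  editing a compound resolves changed components to existing-or-new rows
  and leaves old rows untouched.
* **Mixtures and salts.** A compound is a set of compositions
  (structure + optional percentage). A disconnected input such as
  `[NH+]1=CC=CC=C1.[Br-]` is stored as a mixture of the two ions with
  percentages unset; a structure query matches a compound when at least
  one component matches.
* **Search.** Modes: exact (Full), substructure, SMARTS, similarity
  (Tanimoto `c/(a+b−c)`, Tversky `c/(α(a−c)+β(b−c)+c)`,
  substructure-Euclidean `c/a` on a, b, c = query bits, target bits,
  common bits), and gross formula — each combinable with property
  filters, molecular-weight bounds and sorting. Substructure search is a
  sound fingerprint screen (hashed linear paths, no false negatives)
  followed by exact subgraph verification.
* **Paging and counting.** Results are paged with a deterministic sort;
  the total count of a logical query is computed once and cached in the
  store until a relevant write invalidates it.
* **Planner.** With selective property filters the engine verifies only
  the filtered candidates (`PROPERTY_FIRST`) instead of screening the
  whole structure table (`INDEX_SCREEN`); both strategies return
  identical hit sets.
* **Concurrency and security.** Optimistic locking via a version column;
  optional role-based read filtering compiled into the SQL WHERE clause
  and method-level write guards.

See `docs/methods.md` for the full account and `docs/schema.sql` for the
schema.

## Worked example

```python
from chemreg import (CompoundDatabase, CompoundDraft, SearchRequest,
                     StructureQuery)

db = CompoundDatabase(":memory:").init()
db.save_compound(CompoundDraft(compositions=[("CCO", None)],
                               compound_name="ethanol", cas="64-17-5"),
                 actor="alice")
db.save_compound(CompoundDraft(
    compositions=[("c1ccccc1", 50.0), ("Cc1ccccc1", 50.0)],
    compound_name="benzene/toluene 1:1"), actor="alice")
outcome = db.save_compound(CompoundDraft(
    compositions=[("[NH+]1 = CC = CC = C1.[Br-]", None)],
    compound_name="pyridinium bromide"), actor="alice")
print("salt compositions:",
      [c["structure_key"] for c in outcome.record["compositions"]])
print("structures created/reused:",
      outcome.structures_created, outcome.structures_reused)

page = db.search(SearchRequest(
    target="compound",
    structure=StructureQuery(mode="sub", query_text="c1ccccc1"),
    distinct=True))
print("aromatic hits:", page.total_count,
      [item["compound_name"] for item in page.items])

page = db.search(SearchRequest(
    target="compound",
    structure=StructureQuery(mode="similarity", query_text="OCC",
                             min_score=1.0)))
print("tanimoto 1.0 hits:",
      [item["compound_name"] for item in page.items])
```

Output:

```
salt compositions: ['JUJWROOIHBZHMG-UHFFFAOYSA-O', 'CPELXLSAUQHCOX-UHFFFAOYSA-M']
structures created/reused: 2 0
aromatic hits: 1 ['benzene/toluene 1:1']
tanimoto 1.0 hits: ['ethanol']
```

The salt was split into two ion structures (pyridinium and bromide, each
with its own InChIKey) and stored as a mixture; the benzene substructure
query returns the benzene/toluene mixture exactly once because the
request is `distinct` — with `distinct=False` it would contribute one
row per matching component; the similarity search at threshold 1.0
returns exactly the compound containing ethanol (`OCC` and `CCO` have
identical fingerprints).

The same flows from the shell:

```sh
chemreg --store demo.db init
chemreg --store demo.db gen-fixtures --n 100 --seed 7 --out fix.sdf
chemreg --store demo.db import fix.sdf
chemreg --store demo.db search --mode sub --query c1ccccc1 --page 0
```

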