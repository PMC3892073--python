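# Methods

## Problem and model

chemreg is an embeddable registration-style compound database: it stores
chemical *structures*, *compounds* built from one or more structures
(mixtures), *containables* (batches/lots of a compound) and bar-coded
*containers*, and answers combined structure + property queries with
paging. The design separates three concerns:

1. **Structure identity.** A stored structure is unique and immutable.
   Identity is the standard InChIKey computed from the parsed molecule;
   the key carries a store-level unique constraint, so deduplication is
   enforced by the database, not only by application code. Editing a
   compound never mutates a structure row: the edited component is
   resolved by key to an existing row or a new row is inserted, and the
   old row remains. Structures the InChI algorithm cannot represent fall
   back to `"XK-" + md5(canonical SMILES)` — a deterministic digest that
   preserves the unique-constraint mechanism (collision probability is
   that of a 128-bit hash and is ignored).
2. **Mixtures.** A compound references its components through
   composition rows carrying an optional percentage in (0, 100]. A
   structure query matches a compound when **at least one** component
   matches. An input text with disconnected fragments (a salt such as
   pyridinium bromide) is split and stored as a mixture with percentages
   unset, since the relative amounts are unknown. Duplicate components
   (a di-cation with two identical counter-ions) collapse onto one
   composition per distinct structure: the store keeps one membership
   row per (compound, structure) pair.
3. **No normalization.** Structures are registered as submitted (up to
   canonical SMILES serialization); no tautomer canonicalization, salt
   stripping or other standardization is applied. Applications that need
   it register a pre-save hook, which runs inside the save transaction
   before every create and update.

## Matching and the screening fingerprint

Substructure verification is exact subgraph matching with the toolkit's
default semantics, which we pinned empirically and mirror in the test
oracle: element symbols must agree; bond types (single/double/triple/
aromatic) must agree exactly; a query atom with zero formal charge or
unset isotope is a wildcard for that property, a charged/isotopic query
atom must match exactly; implicit hydrogens on the query do not
constrain the target. SMARTS mode is the escape hatch for precise
constraints.

The screening fingerprint hashes every simple linear atom path of
1..7 atoms into 2048 bits (SHA-1 of the path label, canonical direction
= lexicographic minimum of the two readings). Path labels use **element
symbols and bond types only** — deliberately coarser than the verifier's
atom compatibility — which gives the subset property: if the verifier
embeds Q in T, every labeled path of Q occurs in T, hence
`fp(Q) & fp(T) == fp(Q)`. The screen therefore has no false negatives
and is used as a necessary-condition prune before verification. Paths
never cross components, so a mixture's fingerprint is the bitwise OR of
its components' — exactly what per-component match semantics need.
Parameters (width, maximum path length) are recorded in the config and
in each stored fingerprint's `params_id`; fingerprints with different
parameters are never compared.

Similarity on fingerprints, with a = |A|, b = |B|, c = |A∩B|:
Tanimoto `c/(a+b−c)`; Tversky `c/(α(a−c)+β(b−c)+c)` with the **first
argument as the query**; substructure-Euclidean `c/a`, the fraction of
query bits present in the target (the exact formula behind the
"Euclidean metric for substructures" of chemistry cartridges is not
published; `c/a` is the documented choice here, and Tversky(1,0)
coincides with it). Two empty fingerprints score 1 (0/0 := 1, identity
consistency). Scores are inclusive-bounded into searches via
`min_score`/`max_score`.

## Search, distinct semantics, paging, counting

Without `distinct`, a structure query returns one row per matching
component — a mixture whose two components both match contributes two
rows. `distinct` collapses rows by compound id during candidate
verification (not via SQL DISTINCT), so both planner strategies share
one code path. An application-wide default (`distinct_default`) can
disable distinct processing for single-component databases, where both
result sets provably coincide; a per-request flag overrides it.

Results are fully sorted before paging; `id` ascending is always
appended as a tie-break so page boundaries are deterministic. The total
count of a logical query — the request minus paging and sort, plus the
user's role set — is computed on first execution and cached **in the
store** (table `search_count_cache`), so subsequent pages, including
ones requested by a different process, reuse it. Any compound,
containable or structure write clears the cache (those writes can change
any searchable kind's results through the composition graph); container
writes clear only container entries. Keying the cache per role set
avoids leaking hidden-row counts across privilege levels.

## Query planner

With both a structure query and property filters the engine picks one of
two provably equivalent strategies:

* `INDEX_SCREEN` — scan stored fingerprints, verify survivors, then join
  to compounds and apply filters;
* `PROPERTY_FIRST` — fetch the compounds selected by the (indexed)
  property filters and verify only their components.

Selectivity is estimated from table statistics: `rows/distinct` for
equality filters; for prefix filters, the hit fraction in a
deterministic row-spread sample of ≤256 values (a zero-hit sample is
floored at 1/(2·sample) so rare prefixes still count as rare, never as
impossible); range filters use a flat 0.25 heuristic. `PROPERTY_FIRST`
is chosen when the estimate is ≤ τ·rows (τ = 0.05) and ≤ N_max (5000);
both thresholds are configurable. Verification results are memoized per
structure id within a search, so a structure shared by many candidate
compounds is verified once.

## Concurrency and audit

Every entity row carries created/modified audit columns and an integer
version for optimistic locking: updates put the expected version in the
UPDATE's WHERE clause; zero affected rows signals a concurrent
modification, and a successful update increments the version by exactly
one. All service operations run in a single SQLite transaction
(`BEGIN IMMEDIATE`), so a mid-save failure — including a raising
pre-save hook or a constraint violation on a late insert — rolls back
every table to its prior state.

## Security model

Read filtering is optional. Entities may carry a `read_role`; when
enabled, the predicate `read_role IS NULL OR read_role IN (roles)` is
conjoined into the SQL WHERE clause (never post-filtered), so page
slicing and totals remain consistent and counts cannot leak hidden rows.
Container searches require both the containable's and the compound's
read-role to be readable (conjunction — the stricter of the two
plausible readings). Null `read_role` means world-readable. Writes are
guarded by a configured kind → operation → roles map, deny-by-default
when security is on. Authentication is out of scope; callers construct
the security context.

## SD-files

Records are framed on `$$$$`; `> <tag>` property blocks preserve order
and support multi-line values. Reading is lazy and per-record
fault-contained: malformed records surface as error items and iteration
continues, so one bad entry cannot poison a bulk import (each record is
saved in its own transaction — import is atomic per record, not per
file). Only V2000 connection tables are supported; structures are stored
as canonical SMILES by default (a config switch retains the original
text instead). Export writes mixtures as one multi-fragment mol block
with percentages under a dedicated `percentages` tag, which the importer
maps back positionally; component order is preserved by splitting in
input order on both sides.

## Synthetic data generator

Fixtures emulate a small-molecule registration workload: molecules are
assembled from ring scaffolds (benzene, pyridine, furan, thiophene,
pyrrole, pyrazine, C5/C6 carbocycles, O/N heterocycles) and short
chains, decorated with 0–3 substituents (alkyl, hydroxy, amino, halogen,
nitrile, carboxyl, …) at atoms with free valence — so every structure is
valence-legal by construction. Defaults: 18 heavy atoms maximum, 20%
mixture records of 2–3 components with percentages either unset or
drawn to sum below 100, CAS-like identifiers that are sometimes missing
and occasionally duplicated (the CAS column is deliberately non-unique).
One `random.Random(seed)` drives everything; a given spec yields
byte-identical SD-file output plus a manifest of expected structure-key
sets used as the oracle in round-trip tests.

What the generator does **not** emulate: stereochemistry and isotopic
labels, very large or inorganic species, charged drug-like salts beyond
the worked di-salt examples, and realistic property distributions
(names/CAS are synthetic strings). Passing tests therefore demonstrate
the engine's relational and matching semantics, not chemical coverage of
any vendor catalogue.

## Problem sizes and numerical choices

The test suite exercises stores of 300–2,000 compounds for search
semantics and a 10,000-compound store for the paged five-query harness;
screening soundness uses 500 (target, edge-deleted query) pairs and
matcher/oracle agreement 1,000 pairs of ≤12-heavy-atom molecules —
sizes at which the brute-force VF2 oracle is exhaustive yet the whole
suite runs in well under a minute per criterion. Molecular weights are
average atomic masses from the toolkit's periodic table (reproducible to
0.01 g/mol); percentages are validated by a store CHECK constraint
(0 < p ≤ 100, null = unknown); timestamps are UTC ISO-8601 strings;
formula comparison is on element-count multisets with charge excluded
and Hill normalization applied to both sides.

## Known limitations

* Substructure semantics are the toolkit's default dialect; tautomer and
  resonance matching are not offered.
* The whole-result sort-then-slice pager materializes all hits of a
  query; it is appropriate for embedded stores up to ~10⁵ rows, not for
  a server-scale cartridge.
* Fallback keys ("XK-…") are digest-based: two species that InChI cannot
  represent are distinguished only up to canonical-SMILES equality.
* No schema migrations, soft deletes, or audit history beyond the
  version/metadata columns; deleted compounds leave their structures in
  place (no garbage collection).
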