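# Methods

## Record model and on-disk dialect

A record is a finite tree. Inner nodes are *archetype instances*
(class names of the form `openEHR-EHR-<RMTYPE>.<concept>[.vN][.lbl-NNNNN]`)
and *attributes* (named steps, optionally code-qualified as
`name[atNNNN]`); leaves are scalars (string, number, boolean,
ISO-8601 UTC timestamp as string). On disk each record is one JSON
object: the root archetype object itself, with record metadata under
reserved keys (`record_id`, `ehr_id`, `version`, `active`,
`created_at`, `updated_at`, `structure_id`); archetype objects carry
`archetype_class` and `path_from_parent`; any other key is an
attribute; list-valued attributes are arrays. Extra metadata keys must
start with `_` and are preserved through round trips. Serialization is
deterministic (insertion-ordered keys, compact separators), and
`read(write(r))` reproduces `r` node for node.

Paths are XPath-like chains of attribute steps. Resolution fans out
through arrays (paths never select by list index — predicates filter
values, not positions) and satisfies the composition law
`resolve(n, p+q) = ⋃ resolve(m, q) for m in resolve(n, p)`, with the
empty path as identity.

## Structure canonicalization and the index

`extract_structure` keeps one node per archetype instance, stamped
with its path relative to the nearest archetype ancestor, and discards
everything else. Children are sorted by (class, rendered path,
recursive canonical serialization) — any total order yields
permutation invariance; this one is stable and auditable. The
structure id is the first 16 hex characters of the SHA-256 of the
canonical serialization, making registration idempotent, race-free and
reproducible across processes.

Containment lookup treats the chain patterns as an ordered
subsequence constraint over root-to-node ancestor chains: the chain
may be rooted anywhere in the structure, and any number of archetypes
(including none) may separate consecutive matches. Each matching
structure reports every distinct absolute path to an innermost match
(concatenated `path_from_parent` along the spine), deduplicated and
sorted lexicographically — when several intermediate routes reach the
same innermost node, one path is reported per distinct path, not per
route. A class pattern without a version component matches any version
of the concept; `*` matches anything; benchmark queries use exact ids
only. Lookup reads the registry alone: its cost scales with the number
of distinct structures, never with the record count.

## Query evaluation semantics

The driver examines only records whose structure id matched. Within a
record, the innermost-chain instances are the archetype nodes reached
by the match paths. A record satisfies the query when **some single
innermost instance** satisfies the whole WHERE condition (consistent
binding per instance); predicates on the innermost variable resolve
relative to that instance, predicates on the EHR variable relative to
the record root, and predicates on outer chain variables against any
archetype of the pattern's class. Multi-valued path resolutions give
existential predicate semantics; a missing value makes the predicate
false (three-valued-safe); comparisons apply only between two numbers
or two strings. In fetch mode one row is emitted per satisfying
innermost instance — the chosen granularity when selection paths
multi-resolve — with explicit `None` cells for missing projections,
rows ordered by record id (there is no ORDER BY; determinism is needed
for testing). Count mode counts distinct records; when the query has
no WHERE clause the structure id alone certifies containment and no
record is read at all. In auto mode records are fetched when the count
is at most the fetch threshold (inclusive; default 10 000), otherwise
only counted.

Queries with no CONTAINS clause fall back to all registered structures
with a warning. Stale structure ids in a match list are ignored and
logged.

## Storage drivers

The driver contract covers sessions (idempotent disconnect; operations
on a disconnected session fail cleanly), CRUD with contiguous
versioning, rollback to the previous version, reversible escaping of
store-hostile key characters (`.`, `$`, `%` — percent-encoded),
containers, record split/join, and query execution restricted to index
matches. Exactly the latest active version of each record is
queryable; deleted records keep their history but are hidden, and
their ids are not reusable. A conformance suite (`run_conformance`)
exercises the whole contract and must pass for any new driver; adding
a backend means one factory registration plus the contract
implementation. The names `mongodb` and `elasticsearch` are reserved
in the factory and raise "driver not installed". (A document store
that forbids same-named attributes of different types under one
index/type — as Elasticsearch does — would need per-structure type
names plus an id→type lookup table; that workaround is documented
here but intentionally not implemented.)

The reference driver is in-process with an optional JSON-lines
snapshot. It keeps a secondary hash map from structure id to record
ids — the driver-level realization of "exclude non-matching records
immediately" — and stores records as encoded text, decoding lazily;
this bounds memory per record and makes the records-examined counter
(used by the phase-accounting and baseline tests) explicit.

## Baseline scanner

`baseline.scan` is a serial, streaming re-implementation of the
brute-force comparator: every record of a raw JSON-lines corpus is
examined exactly once, the archetype chain matched recursively, the
condition evaluated per innermost instance. It is written directly
against the JSON dictionaries, sharing no code with the record model
or the driver-side evaluator, so it serves as the independent
correctness oracle — including for the index service's containment
lookups, which are tested against the same chain matcher. Distributed
execution is out of scope; wall-clock comparisons with the indexed
engine are illustrative only.

## Synthetic corpus

The generator emulates heterogeneous pipeline output. Per base
structure:

* **archetype depth** D ~ round(Normal(6.7, 1.7)) truncated to
  [1, 12] (resampling) — at most 12 archetypes on one branch;
* **elements per nesting step**: each nested archetype sits at the end
  of a chain of attribute objects whose length is
  round(Normal(L̄, 1.2)) with L̄ = (66−1)/(6.7−1) ≈ 11.4, so the
  per-structure maximum element depth 1 + Σ Lᵢ has mean ≈ 66 (each
  archetype contributing roughly ten element levels);
* **width** W = 7 + round(exp(Normal(0, 1))), giving mode 8, with a
  1% heavy-tail draw from Uniform(50, 200) so maxima exceed 150. The
  widest level holds W−1 sibling archetypes in one list plus the one
  spine element passing through it, so the realized maximum width is
  exactly W.

The distribution *families* (truncated normal, shifted log-normal) are
this package's choice; only the moments, the mode, the branch cap and
the structure count are fixed by the design. Element depth and width
are measured on the JSON skeleton with arrays transparent: objects and
scalars are elements, an archetype nested at an L-step path sits L
levels below its parent. Exactly 2600 pairwise-distinct canonical
forms are produced (collisions are resampled).

Corpora: CNR plants five datasets of 10% of the corpus each (filler
50%); CL one dataset of 10% (filler 90%), grown in ten equal steps of
identical composition. Each dataset carries its own query-family
classes, planted at a dataset-specific position in the base structures
(progressively deeper along the archetype list), so counts are
identical across placement variants while positions differ. Within a
dataset, every record answers the type-1/2 level-2 queries; nested
prefix bands answer deeper levels and the three WHERE-bearing types,
with per-level fractions interpolated geometrically (ratio
(0.0175/0.10)^{1/3} ≈ 0.559) between the level-2 and level-5
endpoints (0.10 → 0.0175 of the corpus for types 1–2, 0.001 →
0.000175 for types 3–5). Planted counts are
round(fraction · n_records · scale) exactly and are recorded, with the
record-id sets, in the manifest. Responder leaf values are drawn to
satisfy the planted predicates (both conjuncts for AND; alternating
disjuncts for OR); filler records contain no query-family class and
therefore match nothing. Same seed and profile give byte-identical
corpus and manifest.

What the generator does **not** emulate: real clinical content,
terminologies, realistic value distributions, inter-record
correlation, or updates/versioning churn. Passing tests demonstrate
correctness of containment indexing and query evaluation on
structurally realistic trees, not clinical validity of the data.

## Benchmark harness

The harness generates, ingests, then runs the 20-query workload with
per-phase timings (index lookup / count / fetch) as mean ± sd over the
configured repetitions, next to a single baseline scan. A correctness
gate — engine counts and id sets must equal both the baseline and the
manifest — runs first and aborts the benchmark with a diff report on
any disagreement. Timings are single-process and host-dependent; they
are never assertions.

## Problem sizes

Default desk-scale runs: the full 2600-structure library everywhere
its statistics matter; 13k–26k shuffled instances for deduplication
checks; a 3k-record corpus (80 base structures) for engine/baseline
equivalence across all 20 queries and five placement variants; and a
100k-record corpus (1/100 of the design size) for the scaled count
checks, where every scaled count reproduces the full-scale design
exactly except the hit-type level-5 cell, whose exact value 17.5 is
not an integer and rounds to 18.

## Numerical and degenerate-input choices

Numeric literals parse as int/float decimals; scalar comparison is
exact where representable. Booleans never compare numerically.
Duplicate paths from multiple witnesses deduplicate; ties break
lexicographically. Empty corpora, empty registries, empty containment
chains, records with a single archetype and zero attributes, and
malformed corpus lines (counted, skipped, warned) are all defined
inputs. Record ids are caller-supplied; generated ids are sequential
under the corpus seed.

## Known limitations

Full ADL parsing, reference-model typing (DV_QUANTITY etc.), ORDER BY,
TIMEWINDOW, terminology services, template validation, REST service
layer, and production MongoDB/Elasticsearch drivers are out of scope.
The parser accepts exactly the grammar in `docs/aql-grammar.ebnf`.
The CL design's per-query responder fractions reuse the CNR dataset
composition (the design fixes only the 10/90 split).
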