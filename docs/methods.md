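# Methods

This note documents the model behind `brickyard`, the design choices that
were genuinely open, the synthetic inputs the tests run on, and what the
tests do and do not demonstrate.

## The data-package model

A *brick* is a versioned data package: a set of data files (assets), each
identified by the MD5 of its bytes, plus an optional list of other bricks
it depends on. A brick reference is the triple
`(organization, name, commit)`; the commit is the version pin, and two
commits of one brick are treated as entirely distinct packages. This is
deliberate: data dependencies are pinned exactly, so there is no version
*solving* (no ranges, no unification, no conflict resolution) — only
graph closure over exact pins. Consumers that need two versions of a
dataset simply install both; the library path
`org/name/<first 5 commit chars>` keeps them side by side.

Installation is: parse the ref → pin it (registry "latest" lookup for
bare names) → build the transitive dependency graph → topologically sort
it → drop already-installed refs → for each remaining brick, fetch
missing objects into the cache, materialize the brick in a staging
directory, atomically rename it into the library, and write a receipt.

### Why receipts and staging

The upstream protocol this reimplements promises "precisely reproducible"
installs but does not describe failure semantics, so those are defined
here: a receipt file is the *only* thing that makes a brick count as
installed, and it is written after the staged directory has been renamed
into place. Any interruption before that point leaves staging debris
(cleared on the next run) but never a partially-visible brick. The
invariant `receipt ⇔ complete brick` is fault-injection-tested at every
orchestration step.

### Content-addressable cache

All asset bytes live once in `<library>/.cache/<k0k1>/<md5>` (two-level
fan-out avoids huge flat directories) and are hardlinked into brick
directories, with a silent copy fallback where linking is unsupported and
an optional symlink mode. MD5 is retained as the key for fidelity with
the upstream ecosystem; it is a deduplication key, not a security
boundary, and the digest is isolated behind two functions
(`store.file_md5` / `store.bytes_md5`) so a stronger hash could be
substituted without touching callers. The cache is file-granular; chunk
level dedup is out of scope.

### Commit identity in the local registry

The local (directory-backed) registry records each snapshot under its
*content fingerprint*: the MD5 over the canonical `manifest.txt` bytes
followed by the canonical `dependencies.txt` bytes. `fetch_metadata`
recomputes the fingerprint and raises a tamper error on mismatch, which
is how a corrupted or edited snapshot is caught before anything is
installed. Canonical forms matter here: manifests are sorted by relative
path, dependency files by `(org, name, commit)`, both LF/UTF-8, so the
fingerprint is byte-stable. Fingerprints are 32 hex chars, inside the
5–40-char commit grammar; refs pinned to a shorter prefix (≥ 5 chars)
resolve by unique-prefix match.

One consequence is accepted rather than fought: you cannot *choose* a
commit in the fixture registry (it is derived from content), so the
5-char library-prefix collision path is exercised at unit level against
hand-written receipts, and registry fixtures cannot contain dependency
cycles (a cycle would make the fingerprint self-referential). Resolver
cycle handling is tested through in-memory lookup tables instead, which
the resolver accepts by design (its lookup argument is any function).

### Dependency file dialect

`.bb/dependencies.txt` is one `<locator> <commit>` pair per line, `#`
comments, blank lines ignored, canonical writes sorted with a trailing
newline. The upstream dialect is only partially documented, so this one
is *declared*: minimal, diffable, and round-trip-stable
(`parse ∘ write = id` on canonical lists, property-tested).

## The BBT1 triple container

Triple bricks carry RDF-style graphs. Full compatibility with the
compressed HDT binary format was rejected — it is a large specification
whose benefits (bitmap triples, multiple dictionaries) do not pay off at
this scale — in favour of a container that keeps the
header/dictionary/triples idea:

- header: magic `BBT1`, version byte, term count, triple count;
- dictionary: unique terms sorted by UTF-8 bytes, dense 1-based ids,
  one shared dictionary for subjects/predicates/objects (a divergence
  from HDT proper, for simplicity);
- triples: `(s,p,o)` id records as little-endian uint32, strictly sorted
  and deduplicated.

Sorting both sections makes encoding *canonical*: any permutation of the
same triple multiset yields identical bytes, so container bytes can be
content-addressed like any other asset. Bound-subject patterns
(`(s,p,o)`, `(s,p,?)`, `(s,?,?)`) are answered by binary search over the
sorted triple section; other patterns fall back to a scan, and all
patterns are oracle-tested against a brute-force filter. N-Triples
read/write (via rdflib) provides interchange; subjects/predicates must be
IRIs, objects are IRIs when they look like one and plain literals
otherwise. SPARQL and reasoning are out of scope.

## Harmonization

The harmonizer reduces heterogeneous chemical-activity tables to
`substances` / `properties` / `activities`. Each source supplies an
adapter mapping every row to exactly one activity candidate or one
rejection with a reason code; this conservation rule
(`rows_in = activities + rejections`, per source) is the pipeline's main
auditability property and is enforced structurally.

Identifier design was the open question. Row numbers would renumber
everything whenever a source is added, so identifiers are name-based
(version-5) UUIDs: `sid` over the substance's *structure key* — InChI if
present, else SMILES, else `source:local_id` — and `pid` over
`source:property_key`. Adding a source therefore never changes existing
ids, and identical structure strings across sources collapse to one
substance row. **No chemical standardization is performed**: keys compare
as plain strings, so salt forms, tautomers and non-canonical SMILES
remain distinct substances. That is a declared limitation, not an
oversight — canonicalization policy belongs to the data curator, and a
wrong automatic merge is worse than a missed one.

Substance/property metadata is stored as canonical JSON (sorted keys, no
insignificant whitespace, UTF-8); together with deterministic source
ordering (adapter name, then row order; first occurrence wins for shared
substances' metadata) this makes the whole pipeline a pure function of
its inputs — byte-identical outputs on re-runs. "Major" properties are
those with **strictly more** than the threshold's activities (default
1000): a property with exactly 1000 activities is excluded.

## Synthetic inputs

All test and demo inputs are generated (`brickyard.fixtures`), seeded
through `random.Random(str)` so they are identical across platforms and
never committed as data:

- **Registries**: brick specs with per-asset sizes and shared-content
  ids; default scenarios use 2–5 bricks with 64–2048-byte assets —
  enough to express sharing, chains and version coexistence while
  keeping any single test under a second.
- **Dependency DAGs**: up to 20 nodes, edge probability 0.35, 200 seeds
  for the resolver oracle; back-edges injected to provoke cycles.
- **Triple graphs**: up to ~2000 triples with an average term reuse of
  3–4×, the regime where dictionary encoding beats N-Triples text.
- **Chemical sources**: two-three sources with genuinely different column
  layouts (binary assay outcomes, numeric toxicity values with units,
  0/1 screening calls), 20–50 rows each, five compounds shared across
  sources by identical fake InChI strings, and planted invalid rows that
  must surface as rejections. The strings are *shaped* like InChI/SMILES
  but chemically meaningless.

What passing tests therefore show: the protocol's bookkeeping —
deduplication, reproducibility, atomicity, conservation, determinism —
is exact on inputs whose structure (sharing, heterogeneity, corruption)
matches real usage. What they do not show: behaviour at production data
volumes, against remote network backends, or on real chemical curation
questions (near-duplicate structures, unit reconciliation beyond
pass-through).

## Numerical and procedural choices

- Planning ties break lexicographically on `(org, name, commit)`; the
  plan is unique, so logs diff cleanly.
- Dependency-graph traversal depth is capped at 100 (configurable) to
  fail fast on pathological chains.
- `verify` reports corruption as data (a key list), never as an
  exception; `repair` drops bad objects, forgets affected bricks, and
  reinstalls them.
- `gc` deletes exactly the cache keys not referenced by any receipt.
- Empty inputs are first-class: empty dependency files, empty triple
  lists, empty source tables and empty activity tables all round-trip to
  empty outputs rather than errors.

## Known limitations

Remote registry backends (git/HTTP) are pluggable behind
`RegistryBackend` but not shipped; the local directory backend is the
reference implementation. The `push`/review flow for contributing bricks
and the execution of brick *build* pipelines (ETL) are out of scope —
this package installs built assets. MD5's collision weakness is accepted
for protocol fidelity, as discussed above.
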