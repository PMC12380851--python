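# brickyard

A package manager for versioned life-science data assets. Researchers in
toxicology, cheminformatics and public health spend a large fraction of
their time locating, cleaning and re-integrating the same public
databases. `brickyard` treats each dataset as a **brick** — a
commit-pinned package of hashed data files with an explicit dependency
list — and installs bricks the way `pip` or CRAN install code packages:
one command, transitive dependencies resolved, every install exactly
reproducible.

## What it does

- **Commit-pinned identity.** A brick is `organization/name@commit`; its
  library path `org/name/<first 5 commit chars>` encodes all three, so
  multiple versions of one dataset coexist side by side.
- **Content-addressable cache.** Every data file is keyed by its MD5 and
  stored once in a shared cache, then hardlinked into each brick that
  needs it: a file required by five bricks is downloaded and stored one
  time.
- **Deterministic dependency resolution.** Transitive requirements form a
  DAG over pinned refs (no version solving — pins are exact); the install
  plan is a topological order with lexicographic tie-breaking, so it is
  unique and reproducible. Cycles are reported with the offending refs.
- **Atomic installs.** Assets are fetched and materialized in a staging
  directory, renamed into place, and receipted last; an interrupted
  install never leaves a partially-visible brick, and a re-run completes
  from cached objects.
- **Standard asset formats.** Parquet and SQLite for tabular bricks;
  for triple bricks, a compact `BBT1` container (sorted term dictionary +
  sorted integer-id triples) with canonical encoding, binary-search
  pattern queries, and N-Triples interchange.
- **Chemical-activity harmonization.** A pipeline that reduces
  heterogeneous source tables (assay calls, LD50 values, screening hits,
  …) to a three-table schema — `substances(sid, data)`,
  `properties(pid, data)`, `activities(aid, source, sid, pid, value, …)`
  — with structure-keyed substance deduplication (InChI > SMILES > local
  id), stable name-based UUIDs, and per-source row conservation
  (`rows_in = activities + rejections`).

## Worked example

`examples/` contains one short script per capability. Building a demo
registry of three bricks (`abrick -> bbrick -> cbrick`, one file shared
between `abrick` and `bbrick`) and installing the top brick
(`examples/01_install_a_brick.py`) prints:

```
install order: ['demo/cbrick@899ff784...', 'demo/bbrick@c3d0cb28...', 'demo/abrick@0b1b1b43...']
installed bricks: 3
cache objects: 3
re-install executes: 0 bricks (no-op)
```

The install order puts dependencies first; `cache objects: 3` shows
deduplication at work — the three bricks list four asset records, but the
shared file occupies a single cache object. Harmonizing three synthetic
chemical sources (`examples/04_harmonize_sources.py`) prints:

```
substances: 79  properties: 12  activities: 87  rejections: 3
activities by source:
   source  n
  assaydb 38
screenlib 20
  toxvals 29
```

90 input rows are conserved as 87 activities plus 3 rejections (the
planted invalid rows); 79 substances remain after compounds shared across
sources by identical InChI strings collapse to one `sid` each.

A thin CLI mirrors the library (`brickyard configure / install / init /
add / pull / assets / status / verify / gc`), with exit codes 0 ok,
2 user error, 3 registry error, 4 integrity error.

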