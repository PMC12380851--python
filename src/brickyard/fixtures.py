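"""Programmatic generation of every test and demo input.

Nothing in this package's test suite is downloaded or committed as data:
toy brick registries, dependency DAGs, binary blobs, triple graphs and
heterogeneous chemical source tables are all generated here, fully
deterministically under a fixed seed (seeding goes through
``random.Random(str)``, which is platform- and hash-seed-independent).

The chemical sources emulate *schema heterogeneity* — different column
layouts, binary vs numeric values, overlapping compounds identified by
shared InChI strings, planted invalid rows — not chemical plausibility.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from .errors import UserError
from .harmonize import Candidate, Rejection, SourceAdapter
from .refs import (
    AssetRecord,
    BrickManifest,
    BrickRef,
    DependencyList,
    content_fingerprint,
    write_dependency_file,
)
from .registry import LocalRegistry
from .store import bytes_md5

# -- brick registries ------------------------------------------------------


@dataclass
class AssetSpec:
    """One asset in a fixture brick.

    ``content_id`` names the pseudo-random content stream: two assets with
    the same content_id (even across bricks) get byte-identical content,
    which is how shared-file deduplication scenarios are built.
    """

    relative_path: str
    size: int = 256
    content_id: str | None = None
    format_tag: str = "other"


@dataclass
class BrickSpec:
    name: str
    org: str = "demo"
    assets: list[AssetSpec] = field(default_factory=list)
    deps: list[str] = field(default_factory=list)  # keys of other BrickSpecs
    key: str | None = None  # defaults to name; set when a name repeats

    @property
    def spec_key(self) -> str:
        return self.key or self.name


@dataclass
class RegistrySpec:
    seed: int = 0
    bricks: list[BrickSpec] = field(default_factory=list)


@dataclass
class FixtureRegistry:
    """A built on-disk registry plus the pinned refs of its bricks."""

    registry: LocalRegistry
    refs: dict[str, BrickRef]  # spec_key -> pinned ref


def _asset_bytes(seed: int, content_id: str, size: int) -> bytes:
    rng = random.Random(f"asset:{seed}:{content_id}")
    return rng.randbytes(size)


def make_local_registry(
    spec: RegistrySpec, root: Path | str, instrumented: bool = False
) -> FixtureRegistry:
    """Build an on-disk LocalRegistry from a spec; byte-deterministic.

    Bricks are laid down in dependency order (a dependency's commit is
    part of the dependent's fingerprint, so edges must be acyclic). Each
    brick's commit is the content fingerprint of its manifest + dependency
    file; the last spec for a given name becomes its LATEST marker.
    """
    root = Path(root)
    keys = [b.spec_key for b in spec.bricks]
    if len(set(keys)) != len(keys):
        raise UserError(f"duplicate brick spec keys: {keys}")
    by_key = {b.spec_key: b for b in spec.bricks}
    for b in spec.bricks:
        for dep in b.deps:
            if dep not in by_key:
                raise UserError(f"brick {b.spec_key} depends on undefined {dep!r}")

    # topological order over the spec's edges
    order: list[BrickSpec] = []
    done: set[str] = set()
    visiting: set[str] = set()

    def visit(key: str) -> None:
        if key in done:
            return
        if key in visiting:
            raise UserError(f"fixture dependency cycle through {key!r}")
        visiting.add(key)
        for dep in by_key[key].deps:
            visit(dep)
        visiting.discard(key)
        done.add(key)
        order.append(by_key[key])

    for key in keys:
        visit(key)

    objects_dir = root / "objects"
    objects_dir.mkdir(parents=True, exist_ok=True)
    refs: dict[str, BrickRef] = {}
    for brick in order:
        records = []
        for asset in brick.assets:
            cid = asset.content_id or f"{brick.spec_key}/{asset.relative_path}"
            data = _asset_bytes(spec.seed, cid, asset.size)
            key = bytes_md5(data)
            obj = objects_dir / key
            if not obj.exists():
                obj.write_bytes(data)
            records.append(
                AssetRecord(asset.relative_path, key, len(data), asset.format_tag)
            )
        unpinned = BrickRef(brick.org, brick.name)
        manifest_text = BrickManifest(unpinned, tuple(records)).to_text()
        dep_refs = []
        for dep_key in brick.deps:
            dep_ref = refs[dep_key]
            locator = f"https://example.org/{dep_ref.organization}/{dep_ref.name}"
            dep_refs.append(
                BrickRef(dep_ref.organization, dep_ref.name, dep_ref.commit, locator)
            )
        deps_text = write_dependency_file(DependencyList(tuple(dep_refs)))
        commit = content_fingerprint(manifest_text, deps_text)
        snap = root / "bricks" / brick.org / brick.name / commit
        snap.mkdir(parents=True, exist_ok=True)
        (snap / "manifest.txt").write_text(manifest_text, encoding="utf-8")
        (snap / "dependencies.txt").write_text(deps_text, encoding="utf-8")
        (snap.parent / "LATEST").write_text(commit + "\n", encoding="utf-8")
        refs[brick.spec_key] = BrickRef(brick.org, brick.name, commit)

    cls = InstrumentedRegistry if instrumented else LocalRegistry
    return FixtureRegistry(registry=cls(root), refs=refs)


class InstrumentedRegistry(LocalRegistry):
    """LocalRegistry with fetch counters and fault/corruption injection.

    * ``object_reads`` counts backend object reads (a cache hit in the
      sink never reaches the backend, so it never increments this).
    * ``corrupt_keys``: keys served with their first byte flipped, to
      exercise the integrity-error path.
    * ``fail_after_reads``: raise after that many object reads, to
      exercise crash recovery.
    """

    def __init__(self, root, token=None, require_token=False):
        super().__init__(root, token=token, require_token=require_token)
        self.object_reads = 0
        self.metadata_reads = 0
        self.corrupt_keys: set[str] = set()
        self.fail_after_reads: int | None = None

    def fetch_metadata(self, ref):
        self.metadata_reads += 1
        return super().fetch_metadata(ref)

    def _read_object(self, key: str) -> bytes:
        if self.fail_after_reads is not None and self.object_reads >= self.fail_after_reads:
            raise OSError("injected backend failure")
        self.object_reads += 1
        data = super()._read_object(key)
        if key in self.corrupt_keys:
            data = bytes([data[0] ^ 0xFF]) + data[1:]
        return data


# -- random dependency DAGs ------------------------------------------------


def make_random_dag(
    n_nodes: int, edge_prob: float, seed: int
) -> tuple[list[BrickRef], dict[BrickRef, DependencyList]]:
    """A random DAG over fake pinned refs, as (roots, lookup-table).

    Nodes are ordered; edges only point from later to earlier nodes, which
    guarantees acyclicity. Roots are the nodes nothing depends on. The
    lookup table plugs straight into :func:`brickyard.resolver.build_graph`.
    """
    rng = random.Random(f"dag:{seed}")
    nodes = [
        BrickRef("org", f"brick{i:02d}", f"{rng.getrandbits(80):020x}")
        for i in range(n_nodes)
    ]
    deps: dict[BrickRef, list[BrickRef]] = {n: [] for n in nodes}
    depended_on: set[BrickRef] = set()
    for i, node in enumerate(nodes):
        for j in range(i):
            if rng.random() < edge_prob:
                deps[node].append(nodes[j])
                depended_on.add(nodes[j])
    roots = [n for n in nodes if n not in depended_on] or nodes[:1]
    lookup = {n: DependencyList(tuple(ds)) for n, ds in deps.items()}
    return roots, lookup


def inject_back_edge(
    lookup: dict[BrickRef, DependencyList], seed: int
) -> dict[BrickRef, DependencyList] | None:
    """Return a copy of *lookup* with one cycle-creating edge, or None.

    Picks a random existing edge u -> v and adds the reverse edge v -> u.
    Returns None when the DAG has no edges at all.
    """
    rng = random.Random(f"backedge:{seed}")
    edges = [(u, v) for u, deps in lookup.items() for v in deps]
    if not edges:
        return None
    u, v = rng.choice(edges)
    mutated = dict(lookup)
    if u not in mutated[v]:
        mutated[v] = DependencyList(mutated[v].entries + (u,))
    return mutated


# -- triple graphs ---------------------------------------------------------


def make_triple_graph(
    n_triples: int, term_reuse: float = 3.0, seed: int = 0
) -> list[tuple[str, str, str]]:
    """A seeded random triple list (possibly with duplicates).

    Terms are drawn from a pool of about ``3 * n / term_reuse`` IRIs, so
    each term appears ``term_reuse`` times on average — the regime where
    dictionary encoding pays off.
    """
    if n_triples == 0:
        return []
    rng = random.Random(f"triples:{seed}")
    pool_size = max(3, int(3 * n_triples / max(term_reuse, 1e-9)))
    pool = [f"http://example.org/term/{i}" for i in range(pool_size)]
    return [
        (rng.choice(pool), rng.choice(pool), rng.choice(pool))
        for _ in range(n_triples)
    ]


# -- chemical activity sources ---------------------------------------------


@dataclass
class ChemSpec:
    """Shape of the synthetic chemical-activity sources.

    ``rows`` gives the per-source row counts (2-3 sources); ``overlap``
    compounds are shared across all sources by identical InChI strings;
    ``invalid_rows`` plants per-source unmappable rows that must surface
    as rejections.
    """

    seed: int = 0
    rows: tuple[int, ...] = (40, 30, 20)
    overlap: int = 5
    invalid_rows: tuple[int, ...] = (2, 1, 0)
    n_properties: int = 4

    def __post_init__(self) -> None:
        if not 2 <= len(self.rows) <= 3:
            raise UserError("ChemSpec supports 2-3 sources")
        if len(self.invalid_rows) != len(self.rows):
            raise UserError("invalid_rows must align with rows")
        if any(inv > n for inv, n in zip(self.invalid_rows, self.rows)):
            raise UserError("more invalid rows than rows")


def _fake_inchi(i: int) -> str:
    # shaped like an InChI line notation; chemically meaningless
    return f"InChI=1S/C{i % 9 + 1}H{2 * (i % 9 + 1)}O{i % 3}/c{i}"


def _fake_smiles(i: int) -> str:
    return "C" * (i % 5 + 1) + "O" * (i % 3)


class BinaryAssayAdapter(SourceAdapter):
    """Source layout: compound_inchi, assay, outcome ('active'/'inactive')."""

    name = "assaydb"

    def map_row(self, row: Mapping[str, Any]) -> Candidate | Rejection:
        outcome = row.get("outcome")
        if outcome not in ("active", "inactive"):
            return Rejection("bad-outcome")
        if not row.get("compound_inchi"):
            return Rejection("missing-structure")
        return Candidate(
            substance_meta={"inchi": row["compound_inchi"], "source": self.name},
            property_key=str(row["assay"]),
            property_meta={"assay": str(row["assay"]), "kind": "binary assay"},
            value_kind="binary",
            value_binary="positive" if outcome == "active" else "negative",
            inchi=row["compound_inchi"],
        )


class NumericToxAdapter(SourceAdapter):
    """Source layout: chem_smiles, chem_inchi, endpoint, value, unit."""

    name = "toxvals"

    def map_row(self, row: Mapping[str, Any]) -> Candidate | Rejection:
        try:
            value = float(row["value"])
        except (KeyError, TypeError, ValueError):
            return Rejection("bad-value")
        if not row.get("endpoint"):
            return Rejection("missing-property")
        return Candidate(
            substance_meta={
                "smiles": row.get("chem_smiles"),
                "inchi": row.get("chem_inchi"),
            },
            property_key=str(row["endpoint"]),
            property_meta={"endpoint": str(row["endpoint"]), "kind": "tox value"},
            value_kind="numeric",
            value_numeric=value,
            unit=str(row.get("unit", "")),
            smiles=row.get("chem_smiles"),
            inchi=row.get("chem_inchi"),
        )


class ScreenCallAdapter(SourceAdapter):
    """Source layout: cid, structure_smiles, test_name, call (0/1)."""

    name = "screenlib"

    def map_row(self, row: Mapping[str, Any]) -> Candidate | Rejection:
        call = row.get("call")
        if call not in (0, 1):
            return Rejection("bad-call")
        return Candidate(
            substance_meta={"cid": str(row["cid"]), "smiles": row.get("structure_smiles")},
            property_key=str(row["test_name"]),
            property_meta={"test": str(row["test_name"]), "kind": "screen"},
            value_kind="binary",
            value_binary="positive" if call == 1 else "negative",
            smiles=row.get("structure_smiles"),
            local_substance_id=str(row["cid"]),
        )


def make_chem_sources(
    spec: ChemSpec,
) -> list[tuple[SourceAdapter, pd.DataFrame]]:
    """Generate 2-3 heterogeneous chemical-activity source tables.

    The first ``spec.overlap`` compounds (by InChI) appear in every
    source that carries InChI columns; ``spec.invalid_rows[i]`` rows of
    source *i* are planted to fail that source's adapter.
    """
    rng = random.Random(f"chem:{spec.seed}")
    shared = [_fake_inchi(i) for i in range(spec.overlap)]
    adapters: list[SourceAdapter] = [
        BinaryAssayAdapter(),
        NumericToxAdapter(),
        ScreenCallAdapter(),
    ][: len(spec.rows)]
    out: list[tuple[SourceAdapter, pd.DataFrame]] = []
    next_compound = spec.overlap
    for s_idx, (adapter, n_rows, n_invalid) in enumerate(
        zip(adapters, spec.rows, spec.invalid_rows)
    ):
        rows: list[dict[str, Any]] = []
        for r in range(n_rows):
            invalid = r < n_invalid
            if r < spec.overlap and s_idx < 2:
                inchi = shared[r]
                comp = r
            else:
                comp = next_compound
                next_compound += 1
                inchi = _fake_inchi(comp)
            prop = rng.randrange(spec.n_properties)
            if adapter.name == "assaydb":
                rows.append(
                    {
                        "compound_inchi": inchi,
                        "assay": f"AID-{prop}",
                        "outcome": "??" if invalid
                        else rng.choice(["active", "inactive"]),
                    }
                )
            elif adapter.name == "toxvals":
                rows.append(
                    {
                        "chem_smiles": _fake_smiles(comp),
                        "chem_inchi": inchi,
                        "endpoint": f"LD50-{prop}",
                        "value": "not-a-number" if invalid
                        else round(rng.uniform(0.1, 500.0), 3),
                        "unit": "mg/kg",
                    }
                )
            else:  # screenlib has no InChI column: keyed by SMILES/local id
                rows.append(
                    {
                        "cid": f"CID{comp:05d}",
                        "structure_smiles": _fake_smiles(comp),
                        "test_name": f"SCREEN-{prop}",
                        "call": 7 if invalid else rng.choice([0, 1]),
                    }
                )
        out.append((adapter, pd.DataFrame(rows)))
    return out
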