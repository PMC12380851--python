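"""The brick library: resolve -> fetch -> materialize, atomically.

A library is a directory holding one subtree per installed brick at
``org/name/<commit prefix>``, a shared content cache (``.cache``), and one
JSON *receipt* per installed brick (``.receipts``). Receipts are the single
source of truth for what is installed: a brick directory without a receipt
is invisible, which is what makes installs atomic — all fetching and
materialization happens in a staging directory that is renamed into place
only when complete, and the receipt is written last.

Two installs of the same ref from the same registry state produce
byte-identical library trees.
"""

from __future__ import annotations

import json
import logging
import os
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

from . import resolver
from .errors import BrickyardError, CollisionError, UserError
from .refs import (
    AssetRecord,
    BrickManifest,
    BrickRef,
    DependencyList,
    library_path,
    parse_brick_ref,
    parse_dependency_file,
    write_dependency_file,
)
from .registry import RegistryBackend
from .resolver import InstallPlan
from .store import ContentStore, StoreReport, file_md5

log = logging.getLogger(__name__)

#: hook event names emitted during an install, in order, once per brick
INSTALL_EVENTS = ("pre_fetch", "post_fetch", "staged", "pre_commit", "post_commit")


@dataclass
class LibraryStatus:
    """Machine-readable summary of a library."""

    installed: list[BrickRef]
    object_count: int
    total_bytes: int
    orphans: list[str] = field(default_factory=list)


class WorkingBrick:
    """A brick working directory with ``.bb/`` scaffolding."""

    def __init__(self, workdir: os.PathLike | str):
        self.workdir = Path(workdir)

    @property
    def deps_path(self) -> Path:
        return self.workdir / ".bb" / "dependencies.txt"

    @property
    def initialized(self) -> bool:
        return self.deps_path.is_file()

    def dependencies(self) -> DependencyList:
        return parse_dependency_file(self.deps_path.read_text(encoding="utf-8"))


class Library:
    """Orchestrates installs against a registry backend.

    Parameters
    ----------
    root:
        Library root directory (created if absent).
    backend:
        A :class:`~brickyard.registry.RegistryBackend`.
    default_org:
        Organization used for bare-name refs.
    link_mode:
        How assets are materialized from the cache: ``hardlink`` (default,
        with copy fallback), ``copy`` or ``symlink``.
    hook:
        Optional callable ``hook(event, ref)`` invoked at each install
        step (see :data:`INSTALL_EVENTS`); used by fault-injection tests.
    """

    def __init__(
        self,
        root: os.PathLike | str,
        backend: RegistryBackend,
        default_org: str = "local",
        link_mode: str = "hardlink",
        hook: Callable[[str, BrickRef], None] | None = None,
    ):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)
        self.backend = backend
        self.default_org = default_org
        self.link_mode = link_mode
        self._hook = hook or (lambda event, ref: None)
        self.store = ContentStore(self.root / ".cache")
        self._receipts_dir = self.root / ".receipts"
        self._staging_dir = self.root / ".staging"
        self._meta: dict[BrickRef, tuple[BrickManifest, DependencyList]] = {}

    # -- receipts ---------------------------------------------------------

    def _receipt_path(self, ref: BrickRef) -> Path:
        return self._receipts_dir / ref.organization / ref.name / f"{ref.commit}.json"

    def _write_receipt(self, manifest: BrickManifest) -> None:
        ref = manifest.brick_ref
        path = self._receipt_path(ref)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "organization": ref.organization,
            "name": ref.name,
            "commit": ref.commit,
            "installed_at": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
            "assets": [
                {
                    "relative_path": a.relative_path,
                    "md5": a.md5,
                    "byte_size": a.byte_size,
                    "format_tag": a.format_tag,
                }
                for a in manifest.assets
            ],
        }
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", "utf-8")
        os.replace(tmp, path)

    def _receipts(self) -> dict[BrickRef, list[AssetRecord]]:
        out: dict[BrickRef, list[AssetRecord]] = {}
        if not self._receipts_dir.is_dir():
            return out
        for path in sorted(self._receipts_dir.rglob("*.json")):
            data = json.loads(path.read_text("utf-8"))
            ref = BrickRef(data["organization"], data["name"], data["commit"])
            out[ref] = [
                AssetRecord(a["relative_path"], a["md5"], a["byte_size"], a["format_tag"])
                for a in data["assets"]
            ]
        return out

    @property
    def installed(self) -> set[BrickRef]:
        return set(self._receipts())

    def live_keys(self) -> set[str]:
        """All content keys referenced by installed bricks."""
        return {a.md5 for assets in self._receipts().values() for a in assets}

    # -- resolution helpers ----------------------------------------------

    def _metadata(self, ref: BrickRef) -> tuple[BrickManifest, DependencyList]:
        if ref not in self._meta:
            manifest, deps = self.backend.fetch_metadata(ref)
            self._meta[manifest.brick_ref] = (manifest, deps)
            ref = manifest.brick_ref
        return self._meta[ref]

    def resolve(self, ref_text: str | BrickRef) -> BrickRef:
        """Parse, pin (latest if unpinned) and expand to the full commit."""
        ref = (
            parse_brick_ref(ref_text, self.default_org)
            if isinstance(ref_text, str)
            else ref_text
        )
        ref = self.backend.resolve_latest(ref)
        manifest, _ = self._metadata(ref)
        return manifest.brick_ref

    # -- install ----------------------------------------------------------

    def plan_install(self, refs: Iterable[BrickRef]) -> InstallPlan:
        """Full deterministic plan for *refs* and their transitive deps."""
        roots = [self.resolve(r) for r in refs]
        graph = resolver.build_graph(roots, lambda r: self._metadata(r)[1])
        return resolver.plan(graph)

    def install(self, ref_text: str | BrickRef, dry_run: bool = False) -> InstallPlan:
        """Install a brick and its dependencies; returns the executed plan.

        Re-installing an installed ref is a no-op (empty executed plan).
        """
        return self.install_many([ref_text], dry_run=dry_run)

    def install_many(
        self, ref_texts: Iterable[str | BrickRef], dry_run: bool = False
    ) -> InstallPlan:
        refs = [
            parse_brick_ref(r, self.default_org) if isinstance(r, str) else r
            for r in ref_texts
        ]
        full = resolver.diff(self.plan_install(refs), self.installed)
        if dry_run:
            return full
        if self._staging_dir.is_dir():  # leftovers from a crashed run
            shutil.rmtree(self._staging_dir)
        for ref in full:
            self._install_one(ref)
        return full

    def _check_collision(self, ref: BrickRef) -> None:
        prefix_path = self.root / library_path(ref)
        for other in self.installed:
            if (
                other.organization == ref.organization
                and other.name == ref.name
                and other.commit != ref.commit
                and self.root / library_path(other) == prefix_path
            ):
                raise CollisionError(
                    f"commits {other.commit} and {ref.commit} of "
                    f"{ref.organization}/{ref.name} share the 5-char library "
                    "path prefix; use a longer-prefix layout (config option)"
                )

    def _install_one(self, ref: BrickRef) -> None:
        manifest, _ = self._metadata(ref)
        self._check_collision(ref)
        self._hook("pre_fetch", ref)
        for asset in manifest.assets:
            if not self.store.has(asset.md5):
                log.info("fetch %s (%s)", asset.md5, asset.relative_path)
                self.backend.fetch_object(asset.md5, self.store)
        self._hook("post_fetch", ref)
        stage = self._staging_dir / f"{ref.organization}-{ref.name}-{ref.commit}"
        if stage.exists():
            shutil.rmtree(stage)
        stage.mkdir(parents=True)
        for asset in manifest.assets:
            self.store.materialize(asset.md5, stage / asset.relative_path, self.link_mode)
        self._hook("staged", ref)
        final = self.root / library_path(ref)
        final.parent.mkdir(parents=True, exist_ok=True)
        self._hook("pre_commit", ref)
        if final.exists():  # crashed leftover: no receipt, safe to replace
            shutil.rmtree(final)
        os.replace(stage, final)
        self._write_receipt(manifest)
        self._hook("post_commit", ref)
        log.info("installed %s", ref.slug)

    # -- working-brick verbs ----------------------------------------------

    def init(self, workdir: os.PathLike | str) -> WorkingBrick:
        """Create ``.bb/`` scaffolding with an empty dependency file."""
        wb = WorkingBrick(workdir)
        if wb.deps_path.parent.exists():
            raise UserError(f"{wb.workdir} is already initialized")
        wb.deps_path.parent.mkdir(parents=True)
        wb.deps_path.write_text("", encoding="utf-8")
        return wb

    def add(self, workdir: os.PathLike | str, ref_text: str) -> DependencyList:
        """Pin a ref, record it in the dependency file, and install it.

        Adding an already-listed pinned ref is a no-op; on any resolution
        failure the file is left unchanged.
        """
        wb = WorkingBrick(workdir)
        if not wb.initialized:
            raise UserError(f"{wb.workdir} is not initialized (run init first)")
        deps = wb.dependencies()
        ref = self.resolve(ref_text)
        if ref in deps:
            return deps
        updated = DependencyList(deps.entries + (ref,))
        self.install(ref)
        wb.deps_path.write_text(write_dependency_file(updated), encoding="utf-8")
        return wb.dependencies()

    def pull(self, workdir: os.PathLike | str) -> InstallPlan:
        """Install every listed dependency that is not already present."""
        wb = WorkingBrick(workdir)
        if not wb.initialized:
            raise UserError(f"{wb.workdir} is not initialized (run init first)")
        return self.install_many(list(wb.dependencies()))

    # -- inspection --------------------------------------------------------

    def _find_installed(self, ref: BrickRef) -> BrickRef:
        matches = [
            r
            for r in self.installed
            if r.organization == ref.organization
            and r.name == ref.name
            and (ref.commit is None or (r.commit or "").startswith(ref.commit))
        ]
        if not matches:
            raise UserError(
                f"{ref.slug} is not installed; run 'brickyard install {ref.slug}'"
            )
        if len(matches) > 1:
            raise UserError(
                f"{ref.slug} is ambiguous among installed commits: "
                + ", ".join(sorted(r.commit or "" for r in matches))
            )
        return matches[0]

    def assets(self, ref_text: str | BrickRef) -> dict[str, Path]:
        """Absolute paths of an installed brick's assets, keyed by path stem."""
        ref = (
            parse_brick_ref(ref_text, self.default_org)
            if isinstance(ref_text, str)
            else ref_text
        )
        ref = self._find_installed(ref)
        records = self._receipts()[ref]
        base = self.root / library_path(ref)
        out: dict[str, Path] = {}
        for record in records:
            path = base / record.relative_path
            if not path.is_file():
                raise BrickyardError(
                    f"asset {record.relative_path} of {ref.slug} is missing on disk"
                )
            out[Path(record.relative_path).stem] = path.resolve()
        return out

    def status(self) -> LibraryStatus:
        live = self.live_keys()
        return LibraryStatus(
            installed=sorted(self.installed, key=lambda r: r.slug),
            object_count=self.store.object_count,
            total_bytes=self.store.total_bytes,
            orphans=sorted(set(self.store.keys()) - live),
        )

    def verify(self) -> StoreReport:
        return self.store.verify()

    def repair(self, report: StoreReport | None = None) -> int:
        """Drop corrupt cache objects and re-install affected bricks."""
        report = report or self.verify()
        if not report.corrupt:
            return 0
        receipts = self._receipts()
        affected = [
            ref
            for ref, assets in receipts.items()
            if any(a.md5 in report.corrupt for a in assets)
        ]
        for key in report.corrupt:
            self.store.drop(key)
        for ref in affected:
            self._receipt_path(ref).unlink()
            brick_dir = self.root / library_path(ref)
            if brick_dir.exists():
                shutil.rmtree(brick_dir)
        for ref in affected:
            self.install(ref)
        return len(report.corrupt)

    def gc(self) -> int:
        return self.store.gc(self.live_keys())
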