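"""Registry backends: where brick metadata and asset bytes come from.

The backend contract is three capabilities — resolve an unpinned name to
its latest commit, fetch a brick's manifest + dependency list, and fetch a
content object into a store. The :class:`LocalRegistry` backend implements
the contract against a plain directory tree, which makes the entire system
testable offline; remote backends plug in behind the same interface.

A brick snapshot's commit is its content fingerprint — the MD5 over the
canonical manifest and dependency-file bytes — so any tampering with
fetched metadata is detectable by recomputation.
"""

from __future__ import annotations

import abc
import os
from pathlib import Path

from .errors import (
    AuthError,
    BrickNotFoundError,
    IntegrityError,
    RegistryError,
)
from .errors import TamperError
from .refs import (
    BrickManifest,
    BrickRef,
    DependencyList,
    content_fingerprint,
    parse_dependency_file,
)
from .store import ContentStore, bytes_md5


class RegistryBackend(abc.ABC):
    """Contract for brick acquisition.

    Concrete backends implement :meth:`_read_object`; the shared
    :meth:`fetch_object` wrapper enforces the downloaded-only-once
    guarantee (a cached key triggers no backend read at all) and verifies
    received bytes before anything is stored.
    """

    requires_token = False

    @abc.abstractmethod
    def resolve_latest(self, ref: BrickRef) -> BrickRef:
        """Pin an unpinned ref to the backend's designated latest commit.

        Already-pinned refs are returned unchanged.
        """

    @abc.abstractmethod
    def fetch_metadata(self, ref: BrickRef) -> tuple[BrickManifest, DependencyList]:
        """Return manifest + dependency list verified against ref's commit."""

    @abc.abstractmethod
    def _read_object(self, key: str) -> bytes:
        """Return the raw bytes for *key* (backends count/bill this call)."""

    def fetch_object(self, key: str, sink: ContentStore) -> None:
        """Ensure *key* is present in *sink*; skip the read entirely if cached."""
        if sink.has(key):
            return
        data = self._read_object(key)
        if bytes_md5(data) != key:
            raise IntegrityError(
                f"backend served bytes hashing to {bytes_md5(data)}, expected {key}"
            )
        sink.put_bytes(data)


class LocalRegistry(RegistryBackend):
    """Directory-tree registry: brick snapshots plus a shared object pool.

    Layout::

        <root>/bricks/<org>/<name>/<commit>/manifest.txt
        <root>/bricks/<org>/<name>/<commit>/dependencies.txt
        <root>/bricks/<org>/<name>/LATEST      # designated latest commit
        <root>/objects/<md5>                   # object pool

    Commits are full 32-char content fingerprints; refs pinned to a
    shorter prefix (>= 5 chars) are resolved by unique prefix match.
    """

    def __init__(
        self,
        root: os.PathLike | str,
        token: str | None = None,
        require_token: bool = False,
    ):
        self.root = Path(root)
        self.token = token
        self.requires_token = require_token

    # -- helpers ----------------------------------------------------------

    def _check_auth(self) -> None:
        if self.requires_token and not self.token:
            raise AuthError(
                "this registry requires a token; set TOKEN in your config "
                "(brickyard configure --token ...)"
            )

    def _brick_dir(self, ref: BrickRef) -> Path:
        return self.root / "bricks" / ref.organization / ref.name

    def _snapshot_dir(self, ref: BrickRef) -> Path:
        """Locate the snapshot for a (possibly prefix-pinned) ref."""
        base = self._brick_dir(ref)
        if not base.is_dir():
            raise BrickNotFoundError(
                f"brick {ref.organization}/{ref.name} not found in registry {self.root}"
            )
        exact = base / (ref.commit or "")
        if exact.is_dir():
            return exact
        matches = [d for d in sorted(base.iterdir())
                   if d.is_dir() and d.name.startswith(ref.commit or "")]
        if not matches:
            raise BrickNotFoundError(
                f"commit {ref.commit} of {ref.organization}/{ref.name} "
                f"not found in registry {self.root}"
            )
        if len(matches) > 1:
            raise RegistryError(
                f"commit prefix {ref.commit} of {ref.organization}/{ref.name} "
                f"is ambiguous: {[d.name for d in matches]}"
            )
        return matches[0]

    # -- contract ---------------------------------------------------------

    def resolve_latest(self, ref: BrickRef) -> BrickRef:
        if ref.pinned:
            return ref
        self._check_auth()
        marker = self._brick_dir(ref) / "LATEST"
        if not marker.is_file():
            raise BrickNotFoundError(
                f"brick {ref.organization}/{ref.name} not found in registry {self.root}"
            )
        return ref.pin(marker.read_text(encoding="utf-8").strip())

    def fetch_metadata(self, ref: BrickRef) -> tuple[BrickManifest, DependencyList]:
        self._check_auth()
        if not ref.pinned:
            raise RegistryError(f"fetch_metadata requires a pinned ref, got {ref.slug}")
        snap = self._snapshot_dir(ref)
        manifest_text = (snap / "manifest.txt").read_text(encoding="utf-8")
        deps_path = snap / "dependencies.txt"
        deps_text = deps_path.read_text(encoding="utf-8") if deps_path.is_file() else ""
        fingerprint = content_fingerprint(manifest_text, deps_text)
        if fingerprint != snap.name:
            raise TamperError(
                f"metadata for {ref.slug} fingerprints to {fingerprint}, "
                f"but the registry records commit {snap.name}"
            )
        full = ref.pin(snap.name)
        manifest = BrickManifest.from_text(manifest_text, full)
        return manifest, parse_dependency_file(deps_text)

    def _read_object(self, key: str) -> bytes:
        self._check_auth()
        path = self.root / "objects" / key
        if not path.is_file():
            raise BrickNotFoundError(f"object {key} not found in registry {self.root}")
        return path.read_bytes()
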