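"""MD5-keyed content-addressable object store.

Every unique file is stored exactly once under ``<root>/<k0k1>/<md5>``
(two-level fan-out on the first two hex chars) and shared across all bricks
and versions that reference it. MD5 is used as the key for fidelity with
the upstream protocol; it is a dedup key, not a security boundary, and the
digest function is isolated in :func:`file_md5` / :func:`bytes_md5` so a
stronger hash could be swapped in.

Writes are staged to a temporary name and renamed into place, which is
atomic on POSIX filesystems.
"""

from __future__ import annotations

import hashlib
import logging
import os
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .errors import IntegrityError, MissingObjectError

log = logging.getLogger(__name__)

_CHUNK = 1 << 20


def bytes_md5(data: bytes) -> str:
    return hashlib.md5(data).hexdigest()


def file_md5(path: Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        while chunk := fh.read(_CHUNK):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class StoreReport:
    """Result of an integrity scan over (a subset of) the store."""

    object_count: int
    total_bytes: int
    corrupt: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.corrupt


class ContentStore:
    """File-granular object store rooted at a cache directory."""

    def __init__(self, root: os.PathLike | str):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)

    # -- key layout -------------------------------------------------------

    def object_path(self, key: str) -> Path:
        """Stored location is a pure function of the key."""
        return self.root / key[:2] / key

    def has(self, key: str) -> bool:
        return self.object_path(key).is_file()

    def keys(self) -> Iterator[str]:
        for fan in sorted(self.root.iterdir()):
            if fan.is_dir() and len(fan.name) == 2:
                for obj in sorted(fan.iterdir()):
                    yield obj.name

    @property
    def object_count(self) -> int:
        return sum(1 for _ in self.keys())

    @property
    def total_bytes(self) -> int:
        return sum(self.object_path(k).stat().st_size for k in self.keys())

    # -- writes -----------------------------------------------------------

    def put_file(self, path: os.PathLike | str) -> str:
        """Store a file's content under its MD5; idempotent. Returns the key."""
        src = Path(path)
        key = file_md5(src)
        dest = self.object_path(key)
        if dest.is_file():
            return key
        dest.parent.mkdir(parents=True, exist_ok=True)
        tmp = dest.with_name(dest.name + ".tmp")
        shutil.copyfile(src, tmp)
        if file_md5(tmp) != key:  # source changed mid-copy
            tmp.unlink(missing_ok=True)
            raise IntegrityError(f"content of {src} changed while storing")
        os.replace(tmp, dest)
        return key

    def put_bytes(self, data: bytes) -> str:
        key = bytes_md5(data)
        dest = self.object_path(key)
        if dest.is_file():
            return key
        dest.parent.mkdir(parents=True, exist_ok=True)
        tmp = dest.with_name(dest.name + ".tmp")
        tmp.write_bytes(data)
        os.replace(tmp, dest)
        return key

    def read_bytes(self, key: str) -> bytes:
        if not self.has(key):
            raise MissingObjectError(f"object {key} not in store")
        return self.object_path(key).read_bytes()

    # -- materialization --------------------------------------------------

    def materialize(
        self, key: str, dest: os.PathLike | str, mode: str = "hardlink"
    ) -> None:
        """Make the object's content visible at *dest*.

        Hardlink by default (one object, many visible files); falls back to
        a copy when linking is unsupported (e.g. cross-device). Re-running
        over an up-to-date *dest* is a no-op.
        """
        if mode not in ("hardlink", "copy", "symlink"):
            raise ValueError(f"unknown materialize mode {mode!r}")
        src = self.object_path(key)
        if not src.is_file():
            raise MissingObjectError(f"object {key} not in store")
        dest = Path(dest)
        if dest.is_file() and file_md5(dest) == key:
            return
        dest.parent.mkdir(parents=True, exist_ok=True)
        dest.unlink(missing_ok=True)
        if mode == "symlink":
            dest.symlink_to(src.resolve())
        elif mode == "copy":
            shutil.copyfile(src, dest)
        else:
            try:
                os.link(src, dest)
            except OSError as exc:
                log.debug("hardlink failed (%s); copying %s", exc, key)
                shutil.copyfile(src, dest)

    # -- maintenance ------------------------------------------------------

    def verify(self, keys: Iterable[str] | None = None) -> StoreReport:
        """Re-hash stored objects; corruption is reported, never raised."""
        scan = list(keys) if keys is not None else list(self.keys())
        corrupt = []
        total = 0
        count = 0
        for key in scan:
            path = self.object_path(key)
            if not path.is_file():
                continue
            count += 1
            total += path.stat().st_size
            if file_md5(path) != key:
                corrupt.append(key)
        return StoreReport(object_count=count, total_bytes=total, corrupt=corrupt)

    def drop(self, key: str) -> None:
        self.object_path(key).unlink(missing_ok=True)

    def gc(self, live_keys: set[str]) -> int:
        """Delete objects not in *live_keys*; returns the number removed."""
        removed = 0
        for key in list(self.keys()):
            if key not in live_keys:
                self.drop(key)
                removed += 1
        return removed
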