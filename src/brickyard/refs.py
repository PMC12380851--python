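"""Brick identity, manifests, and the dependency-file dialect.

A *brick* is a versioned data package identified by ``organization/name``
plus a commit hash pin. The library path of an installed brick encodes all
three (``org/name/<first 5 commit chars>``), so multiple versions of the
same dataset coexist side by side.

Two on-disk text dialects are defined here and kept byte-deterministic:

``manifest.txt``
    one line per asset: ``<md5> <byte_size> <format_tag> <relative_path>``,
    sorted by relative path, LF line endings, UTF-8. The MD5 of this file
    (together with the dependency file) serves as the brick's content
    fingerprint.

``.bb/dependencies.txt``
    one line per required brick: ``<locator> <commit>``; ``#`` comments and
    blank lines ignored on read; canonical writes sort entries.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field

from .errors import BrickParseError, DependencyFileError, ManifestError

_NAME_RE = re.compile(r"^[A-Za-z0-9._-]+$")
_COMMIT_RE = re.compile(r"^[0-9a-f]{5,40}$")
_MD5_RE = re.compile(r"^[0-9a-f]{32}$")

#: asset format tags recognised in manifests
FORMAT_TAGS = ("parquet", "sqlite", "triples", "other")

#: first-N commit characters used in library paths
COMMIT_PREFIX_LEN = 5


@dataclass(frozen=True, order=True)
class BrickRef:
    """Identity of a brick: organization, name and an optional commit pin.

    Two refs are equal iff ``(organization, name, commit)`` are equal; the
    same name at two different commits is two distinct refs. ``commit=None``
    marks an *unpinned* ref, to be resolved to a concrete commit by a
    registry before planning.
    """

    organization: str
    name: str
    commit: str | None = None
    source_locator: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for label, token in (("organization", self.organization), ("name", self.name)):
            if not token or not _NAME_RE.match(token):
                raise BrickParseError(f"invalid {label} token: {token!r}")
        if self.commit is not None and not _COMMIT_RE.match(self.commit):
            raise BrickParseError(
                f"invalid commit {self.commit!r}: expected 5-40 lowercase hex chars"
            )

    @property
    def pinned(self) -> bool:
        return self.commit is not None

    @property
    def slug(self) -> str:
        """``org/name`` or ``org/name@commit``."""
        base = f"{self.organization}/{self.name}"
        return f"{base}@{self.commit}" if self.commit else base

    def pin(self, commit: str) -> "BrickRef":
        return BrickRef(self.organization, self.name, commit, self.source_locator)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.slug


def _org_name_from_locator(locator: str) -> tuple[str, str]:
    """Extract (organization, name) from a URL or ``org/name`` identifier."""
    body = locator
    if "://" in body:
        body = body.split("://", 1)[1]
        parts = [p for p in body.split("/") if p][1:]  # drop the host
    else:
        parts = [p for p in body.split("/") if p]
    if len(parts) < 2:
        raise BrickParseError(
            f"cannot derive organization/name from locator {locator!r}"
        )
    org, name = parts[-2], parts[-1]
    if name.endswith(".git"):
        name = name[: -len(".git")]
    return org, name


def parse_brick_ref(text: str, default_org: str) -> BrickRef:
    """Parse a user-supplied brick reference.

    Accepted forms: ``name``, ``org/name``, ``org/name@commit`` and a full
    locator ``url#commit`` (or a bare URL, left unpinned). A bare ``name``
    takes its organization from *default_org*; an absent commit leaves the
    ref unpinned for later latest-commit resolution.
    """
    text = text.strip()
    if not text:
        raise BrickParseError("empty brick reference")
    if not _NAME_RE.match(default_org):
        raise BrickParseError(f"invalid default organization: {default_org!r}")

    commit: str | None = None
    locator: str | None = None
    body = text
    if "#" in text:
        body, commit = text.rsplit("#", 1)
    elif "@" in text:
        body, commit = text.rsplit("@", 1)
    if commit is not None and not _COMMIT_RE.match(commit):
        raise BrickParseError(f"invalid commit {commit!r} in reference {text!r}")

    if "://" in body:
        locator = body
        org, name = _org_name_from_locator(body)
    else:
        parts = [p for p in body.split("/") if p]
        if len(parts) == 1:
            org, name = default_org, parts[0]
        elif len(parts) == 2:
            org, name = parts
        else:
            raise BrickParseError(f"malformed brick reference: {text!r}")
    return BrickRef(org, name, commit, locator)


def library_path(ref: BrickRef) -> str:
    """Relative library path ``org/name/<commit prefix>`` for a pinned ref."""
    if not ref.pinned:
        raise BrickParseError(f"cannot derive a library path for unpinned ref {ref.slug}")
    return f"{ref.organization}/{ref.name}/{ref.commit[:COMMIT_PREFIX_LEN]}"


@dataclass(frozen=True)
class AssetRecord:
    """One data file in a brick: where it lives and what bytes it must be."""

    relative_path: str
    md5: str
    byte_size: int
    format_tag: str = "other"

    def __post_init__(self) -> None:
        p = self.relative_path
        if not p or p.startswith("/") or p != p.strip():
            raise ManifestError(f"invalid asset path: {p!r}")
        if any(seg == ".." for seg in p.split("/")) or "\n" in p:
            raise ManifestError(f"invalid asset path: {p!r}")
        if not _MD5_RE.match(self.md5):
            raise ManifestError(f"invalid md5 for {p!r}: {self.md5!r}")
        if self.byte_size < 0:
            raise ManifestError(f"negative byte size for {p!r}")
        if self.format_tag not in FORMAT_TAGS:
            raise ManifestError(f"unknown format tag {self.format_tag!r} for {p!r}")


@dataclass(frozen=True)
class BrickManifest:
    """A brick's asset list in canonical (path-sorted) order."""

    brick_ref: BrickRef
    assets: tuple[AssetRecord, ...]
    description: str | None = None

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.assets, key=lambda a: a.relative_path))
        object.__setattr__(self, "assets", ordered)
        paths = [a.relative_path for a in ordered]
        if len(set(paths)) != len(paths):
            dupes = sorted({p for p in paths if paths.count(p) > 1})
            raise ManifestError(f"duplicate asset paths in manifest: {dupes}")

    def to_text(self) -> str:
        """Canonical ``manifest.txt`` serialization (byte-deterministic)."""
        lines = [
            f"{a.md5} {a.byte_size} {a.format_tag} {a.relative_path}"
            for a in self.assets
        ]
        return "".join(line + "\n" for line in lines)

    @classmethod
    def from_text(cls, text: str, brick_ref: BrickRef) -> "BrickManifest":
        records = []
        for lineno, raw in enumerate(text.splitlines(), start=1):
            if not raw.strip():
                continue
            parts = raw.split(" ", 3)
            if len(parts) != 4:
                raise ManifestError(f"manifest line {lineno}: expected 4 fields")
            md5, size, tag, path = parts
            try:
                byte_size = int(size)
            except ValueError:
                raise ManifestError(f"manifest line {lineno}: bad byte size {size!r}")
            records.append(AssetRecord(path, md5, byte_size, tag))
        return cls(brick_ref, tuple(records))


def content_fingerprint(manifest_text: str, dependencies_text: str) -> str:
    """MD5 fingerprint over the canonical manifest + dependency file bytes.

    This is the commit identity a local registry records for a brick
    snapshot: any edit to either file changes the fingerprint, which is how
    tampering is detected on fetch.
    """
    h = hashlib.md5()
    h.update(manifest_text.encode("utf-8"))
    h.update(dependencies_text.encode("utf-8"))
    return h.hexdigest()


@dataclass(frozen=True)
class DependencyList:
    """Ordered, duplicate-free list of pinned brick requirements."""

    entries: tuple[BrickRef, ...] = ()

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, str | None]] = set()
        for ref in self.entries:
            key = (ref.organization, ref.name, ref.commit)
            if key in seen:
                raise DependencyFileError(f"duplicate dependency: {ref.slug}")
            seen.add(key)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, ref: BrickRef) -> bool:
        return ref in self.entries


def parse_dependency_file(text: str) -> DependencyList:
    """Parse a ``dependencies.txt``: ``<locator> <commit>`` per line.

    Blank lines and ``#`` comments are skipped; extra whitespace is
    tolerated. File order is preserved. Errors name the offending line.
    """
    entries: list[BrickRef] = []
    seen: set[tuple[str, str, str]] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 2:
            raise DependencyFileError(
                f"line {lineno}: expected '<locator> <commit>', got {raw!r}"
            )
        locator, commit = fields
        if not _COMMIT_RE.match(commit):
            raise DependencyFileError(f"line {lineno}: invalid commit {commit!r}")
        try:
            org, name = _org_name_from_locator(locator)
            ref = BrickRef(org, name, commit, locator)
        except BrickParseError as exc:
            raise DependencyFileError(f"line {lineno}: {exc}") from exc
        key = (org, name, commit)
        if key in seen:
            raise DependencyFileError(f"line {lineno}: duplicate dependency {ref.slug}")
        seen.add(key)
        entries.append(ref)
    return DependencyList(tuple(entries))


def write_dependency_file(deps: DependencyList) -> str:
    """Canonical serialization: sorted by (org, name, commit), one per line."""
    ordered = sorted(deps, key=lambda r: (r.organization, r.name, r.commit or ""))
    lines = []
    for ref in ordered:
        locator = ref.source_locator or f"{ref.organization}/{ref.name}"
        if not ref.pinned:
            raise DependencyFileError(f"cannot serialize unpinned dependency {ref.slug}")
        lines.append(f"{locator} {ref.commit}")
    return "".join(line + "\n" for line in lines)
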