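"""Asset format identification and the dictionary-encoded triple container.

Bricks standardize on a small set of formats: Parquet and SQLite for
tabular assets, and a compressed triple store for RDF-style graphs.
For triples this package defines ``BBT1``, a deliberately simple
header/dictionary/triples container in the spirit of compressed RDF
serializations (it is NOT the W3C HDT binary format):

* header — magic ``BBT1``, version byte, term and triple counts;
* dictionary — the unique terms, sorted by UTF-8 bytes, with dense
  1-based integer ids (one shared dictionary for subjects, predicates
  and objects);
* triples — ``(s_id, p_id, o_id)`` little-endian uint32 records, strictly
  sorted and deduplicated.

Because both sections are sorted, encoding is canonical: any permutation
of the same triple multiset produces identical bytes, and bound-subject
pattern queries run by binary search over the triple section.

N-Triples files (via rdflib) provide interchange with standard RDF
tooling.
"""

from __future__ import annotations

import os
import struct
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from pathlib import Path

import pyarrow.parquet as pq
import rdflib

from .errors import BrickyardError, UserError

MAGIC = b"BBT1"
_VERSION = 1

_MAGIC_PARQUET = b"PAR1"
_MAGIC_SQLITE = b"SQLite format 3\x00"

StrTriple = tuple[str, str, str]


def sniff_format(path: os.PathLike | str) -> str:
    """Classify a file as parquet / sqlite / triples / other by magic bytes."""
    with open(path, "rb") as fh:
        head = fh.read(16)
    if head.startswith(_MAGIC_PARQUET):
        return "parquet"
    if head.startswith(_MAGIC_SQLITE):
        return "sqlite"
    if head.startswith(MAGIC):
        return "triples"
    return "other"


@dataclass(frozen=True)
class TripleContainer:
    """Decoded container: sorted term dictionary + sorted id-triples."""

    terms: tuple[str, ...]
    triples: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        n = len(self.terms)
        if list(self.terms) != sorted(set(self.terms), key=lambda t: t.encode()):
            raise BrickyardError("dictionary terms not sorted/unique")
        if list(self.triples) != sorted(set(self.triples)):
            raise BrickyardError("triple list not strictly sorted")
        for t in self.triples:
            if not all(1 <= i <= n for i in t):
                raise BrickyardError(f"triple id out of dictionary range: {t}")

    def term_id(self, term: str) -> int | None:
        """1-based id of *term*, or None if absent (binary search)."""
        i = bisect_left(self.terms, term.encode(), key=lambda t: t.encode())
        if i < len(self.terms) and self.terms[i] == term:
            return i + 1
        return None

    def to_string_triples(self) -> list[StrTriple]:
        t = self.terms
        return [(t[s - 1], t[p - 1], t[o - 1]) for s, p, o in self.triples]

    def __len__(self) -> int:
        return len(self.triples)


def encode_triples(triples: list[StrTriple]) -> bytes:
    """Serialize string triples to canonical ``BBT1`` bytes.

    Duplicates are removed; the output is a pure function of the input
    triple *set*.
    """
    for t in triples:
        if len(t) != 3 or any(not isinstance(x, str) or not x for x in t):
            raise UserError(f"triple terms must be nonempty strings: {t!r}")
    terms = sorted({x for t in triples for x in t}, key=lambda s: s.encode())
    ids = {term: i + 1 for i, term in enumerate(terms)}
    id_triples = sorted({(ids[s], ids[p], ids[o]) for s, p, o in triples})
    out = bytearray()
    out += MAGIC
    out += struct.pack("<BII", _VERSION, len(terms), len(id_triples))
    for term in terms:
        b = term.encode("utf-8")
        out += struct.pack("<I", len(b)) + b
    for t in id_triples:
        out += struct.pack("<III", *t)
    return bytes(out)


def decode_triples(data: bytes) -> TripleContainer:
    """Parse ``BBT1`` bytes back into a validated container."""
    if data[:4] != MAGIC:
        raise BrickyardError("not a BBT1 container (bad magic)")
    version, n_terms, n_triples = struct.unpack_from("<BII", data, 4)
    if version != _VERSION:
        raise BrickyardError(f"unsupported BBT1 version {version}")
    offset = 4 + struct.calcsize("<BII")
    terms = []
    for _ in range(n_terms):
        (length,) = struct.unpack_from("<I", data, offset)
        offset += 4
        terms.append(data[offset: offset + length].decode("utf-8"))
        offset += length
    triples = []
    for _ in range(n_triples):
        triples.append(struct.unpack_from("<III", data, offset))
        offset += 12
    if offset != len(data):
        raise BrickyardError("trailing bytes after BBT1 triple section")
    return TripleContainer(tuple(terms), tuple(triples))


def query_triples(
    container: TripleContainer,
    pattern: tuple[str | None, str | None, str | None],
) -> list[StrTriple]:
    """All triples matching a pattern; ``None`` is a wildcard.

    Patterns bound on a subject prefix — ``(s, p, o)``, ``(s, p, ?)`` and
    ``(s, ?, ?)`` — are answered by binary search over the sorted triple
    list; the rest fall back to a filtered scan. An unknown term yields an
    empty result.
    """
    s, p, o = pattern
    ids: list[int | None] = []
    for term in (s, p, o):
        if term is None:
            ids.append(None)
        else:
            i = container.term_id(term)
            if i is None:
                return []
            ids.append(i)
    si, pi, oi = ids
    terms = container.terms

    def render(rows) -> list[StrTriple]:
        return [(terms[a - 1], terms[b - 1], terms[c - 1]) for a, b, c in rows]

    if si is not None:
        # prefix-bound: slice the sorted list between lower and upper bounds
        if pi is not None:
            lo_key, hi_key = (si, pi, oi or 0), (si, pi, oi or 2**32)
        else:
            lo_key, hi_key = (si, 0, 0), (si, 2**32, 2**32)
        lo = bisect_left(container.triples, lo_key)
        hi = bisect_right(container.triples, hi_key)
        rows = container.triples[lo:hi]
    else:
        rows = container.triples
    rows = [
        r
        for r in rows
        if (pi is None or r[1] == pi) and (oi is None or r[2] == oi)
    ]
    return render(rows)


# -- N-Triples interchange ------------------------------------------------

_IRI_SCHEMES = ("http://", "https://", "urn:", "file://", "ftp://")


def _looks_like_iri(term: str) -> bool:
    return term.startswith(_IRI_SCHEMES)


def write_ntriples(triples: list[StrTriple], path: os.PathLike | str) -> None:
    """Write triples as N-Triples.

    Subjects and predicates must be IRIs; objects are written as IRIs when
    they look like one and as plain literals otherwise.
    """
    g = rdflib.Graph()
    for s, p, o in triples:
        if not (_looks_like_iri(s) and _looks_like_iri(p)):
            raise UserError(f"N-Triples subject/predicate must be IRIs: {(s, p, o)!r}")
        obj = rdflib.URIRef(o) if _looks_like_iri(o) else rdflib.Literal(o)
        g.add((rdflib.URIRef(s), rdflib.URIRef(p), obj))
    Path(path).write_bytes(g.serialize(format="nt", encoding="utf-8"))


def read_ntriples(path: os.PathLike | str) -> list[StrTriple]:
    """Read an N-Triples file into string triples (sorted, deduplicated)."""
    g = rdflib.Graph()
    g.parse(str(path), format="nt")
    out = {(str(s), str(p), str(o)) for s, p, o in g}
    return sorted(out)


# -- partitioned tabular checks -------------------------------------------

@dataclass
class PartitionReport:
    """Schema-consistency and row-count report for a partitioned table."""

    total_rows: int
    part_count: int
    mismatches: list[str]

    @property
    def ok(self) -> bool:
        return not self.mismatches


def check_partitioned_table(directory: os.PathLike | str) -> PartitionReport:
    """Validate a directory of Parquet part-files as one logical table.

    All parts must share column names and types (the first part, in
    filename order, is the reference); total rows is the sum over parts.
    """
    parts = sorted(Path(directory).glob("*.parquet"))
    if not parts:
        raise UserError(f"no parquet part-files in {directory}")
    reference = pq.read_schema(parts[0]).remove_metadata()
    total = 0
    mismatches = []
    for part in parts:
        pf = pq.ParquetFile(part)
        total += pf.metadata.num_rows
        schema = pf.schema_arrow.remove_metadata()
        if not schema.equals(reference):
            mismatches.append(part.name)
    return PartitionReport(total_rows=total, part_count=len(parts), mismatches=mismatches)
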