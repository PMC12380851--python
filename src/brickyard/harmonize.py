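"""Harmonization of heterogeneous chemical-activity sources.

Many chemical-safety databases record, in wildly different schemas, the
same kind of fact: *substance S has value V for property P* — an assay
outcome, an LD50, a binding affinity. This module reduces any number of
such sources to one three-table schema:

``substances``
    ``sid`` (stable substance identifier) + a canonical-JSON column of
    source-provided substance metadata (typically SMILES and/or InChI).
``properties``
    ``pid`` + a canonical-JSON column of property metadata.
``activities``
    one row per measurement linking a ``sid`` to a ``pid`` with either a
    binary value (positive/negative) or a numeric value with a unit, plus
    pass-through SMILES/InChI columns for downstream modeling.

Identifiers are name-based (version-5) UUIDs so re-harmonizing after
adding a source leaves existing sids and pids unchanged:

* ``sid`` is keyed on the substance's *structure key* — InChI if present,
  else SMILES, else ``source:local_id``. Identical structure strings
  across sources therefore collapse to one substance row. No chemical
  standardization (canonical SMILES, salt stripping, tautomer merging) is
  performed: keys compare as plain strings.
* ``pid`` is keyed on ``source:property_key`` (properties are per-source).

Each source is driven by a :class:`SourceAdapter`, which maps every input
row to exactly one activity candidate OR one rejection (with a reason
code), so rows are conserved: ``rows_in == activities_out +
rejections_out`` per source. The whole pipeline is a pure function of its
inputs — same tables in, byte-identical tables out.
"""

from __future__ import annotations

import abc
import json
import uuid
from dataclasses import dataclass
from typing import Any, Iterable, Mapping

import pandas as pd

from .errors import UserError

_NS = uuid.UUID("6ba7b810-9dad-11d1-80b4-00c04fd430c8")  # RFC 4122 DNS namespace
SUBSTANCE_NS = uuid.uuid5(_NS, "brickyard/substance")
PROPERTY_NS = uuid.uuid5(_NS, "brickyard/property")
ACTIVITY_NS = uuid.uuid5(_NS, "brickyard/activity")

#: strictly-greater-than cutoff for a "major" property
MAJOR_PROPERTY_THRESHOLD = 1000


def canonical_json(obj: Mapping[str, Any]) -> str:
    """Sorted-key, no-whitespace, UTF-8 JSON — byte-deterministic."""
    return json.dumps(obj, sort_keys=True, separators=(",", ":"), ensure_ascii=False)


@dataclass(frozen=True)
class Candidate:
    """One mapped activity before id assignment."""

    substance_meta: Mapping[str, Any]
    property_key: str
    property_meta: Mapping[str, Any]
    value_kind: str  # "binary" | "numeric"
    value_binary: str | None = None  # "positive" | "negative"
    value_numeric: float | None = None
    unit: str | None = None
    smiles: str | None = None
    inchi: str | None = None
    local_substance_id: str | None = None


@dataclass(frozen=True)
class Rejection:
    """A row the adapter could not map, with a machine-readable reason."""

    reason: str


class SourceAdapter(abc.ABC):
    """Maps one source table's rows to candidates or rejections."""

    name: str

    @abc.abstractmethod
    def map_row(self, row: Mapping[str, Any]) -> Candidate | Rejection:
        """Return exactly one Candidate or one Rejection for *row*."""


@dataclass
class HarmonyTables:
    """The harmonized 3-table schema plus the per-source rejection log."""

    substances: pd.DataFrame  # sid, data
    properties: pd.DataFrame  # pid, data
    activities: pd.DataFrame  # aid, source, sid, pid, value_kind, ...
    rejections: pd.DataFrame  # source, row_index, reason

    def to_canonical_csv(self) -> dict[str, bytes]:
        """Deterministic CSV bytes per table (for fingerprinting outputs)."""
        return {
            name: df.to_csv(index=False).encode("utf-8")
            for name, df in (
                ("substances", self.substances),
                ("properties", self.properties),
                ("activities", self.activities),
                ("rejections", self.rejections),
            )
        }


_ACTIVITY_COLUMNS = [
    "aid",
    "source",
    "sid",
    "pid",
    "value_kind",
    "value_binary",
    "value_numeric",
    "unit",
    "smiles",
    "inchi",
]


def _structure_key(source: str, cand: Candidate) -> str:
    if cand.inchi:
        return f"inchi:{cand.inchi}"
    if cand.smiles:
        return f"smiles:{cand.smiles}"
    if cand.local_substance_id:
        return f"local:{source}:{cand.local_substance_id}"
    raise UserError(
        f"adapter {source!r} emitted a candidate with no structure key "
        "(need inchi, smiles or local_substance_id)"
    )


def _validate_candidate(source: str, index: int, cand: Candidate) -> None:
    binary_ok = cand.value_kind == "binary" and cand.value_binary in (
        "positive",
        "negative",
    ) and cand.value_numeric is None
    numeric_ok = (
        cand.value_kind == "numeric"
        and cand.value_numeric is not None
        and cand.value_binary is None
    )
    if not (binary_ok or numeric_ok):
        raise UserError(
            f"adapter contract violation in source {source!r}, row {index}: "
            f"value_kind={cand.value_kind!r}, value_binary={cand.value_binary!r}, "
            f"value_numeric={cand.value_numeric!r}"
        )


def harmonize(
    sources: Iterable[tuple[SourceAdapter, pd.DataFrame]],
) -> HarmonyTables:
    """Merge heterogeneous source tables into the 3-table schema.

    Sources are processed in adapter-name order and rows in table order,
    so the output (including which source's metadata wins for a shared
    substance: first occurrence) is deterministic.
    """
    sources = sorted(sources, key=lambda pair: pair[0].name)
    if not sources:
        raise UserError("harmonize needs at least one source")
    names = [a.name for a, _ in sources]
    if len(set(names)) != len(names):
        raise UserError(f"duplicate source names: {names}")

    substances: dict[str, str] = {}  # sid -> canonical JSON
    properties: dict[str, str] = {}
    activities: list[dict[str, Any]] = []
    rejections: list[dict[str, Any]] = []

    for adapter, table in sources:
        source = adapter.name
        for index, row in enumerate(table.to_dict(orient="records")):
            mapped = adapter.map_row(row)
            if isinstance(mapped, Rejection):
                rejections.append(
                    {"source": source, "row_index": index, "reason": mapped.reason}
                )
                continue
            _validate_candidate(source, index, mapped)
            skey = _structure_key(source, mapped)
            sid = str(uuid.uuid5(SUBSTANCE_NS, skey))
            substances.setdefault(sid, canonical_json(dict(mapped.substance_meta)))
            pid = str(uuid.uuid5(PROPERTY_NS, f"{source}:{mapped.property_key}"))
            properties.setdefault(pid, canonical_json(dict(mapped.property_meta)))
            aid = str(uuid.uuid5(ACTIVITY_NS, f"{source}:{index}"))
            activities.append(
                {
                    "aid": aid,
                    "source": source,
                    "sid": sid,
                    "pid": pid,
                    "value_kind": mapped.value_kind,
                    "value_binary": mapped.value_binary,
                    "value_numeric": mapped.value_numeric,
                    "unit": mapped.unit,
                    "smiles": mapped.smiles,
                    "inchi": mapped.inchi,
                }
            )

    substances_df = pd.DataFrame(
        sorted(substances.items()), columns=["sid", "data"]
    )
    properties_df = pd.DataFrame(
        sorted(properties.items()), columns=["pid", "data"]
    )
    activities_df = pd.DataFrame(activities, columns=_ACTIVITY_COLUMNS)
    activities_df = activities_df.sort_values(
        ["source", "sid", "pid", "aid"], kind="mergesort"
    ).reset_index(drop=True)
    rejections_df = pd.DataFrame(
        rejections, columns=["source", "row_index", "reason"]
    )
    return HarmonyTables(substances_df, properties_df, activities_df, rejections_df)


def count_activities_by_source(activities: pd.DataFrame) -> pd.DataFrame:
    """Exact activity counts per source, sorted by source name."""
    if activities.empty:
        return pd.DataFrame(columns=["source", "n"])
    counts = (
        activities.groupby("source", sort=True).size().rename("n").reset_index()
    )
    counts["n"] = counts["n"].astype(int)
    return counts


def major_properties(
    activities: pd.DataFrame, threshold: int = MAJOR_PROPERTY_THRESHOLD
) -> list[str]:
    """pids with strictly more than *threshold* activities, sorted.

    A property with exactly *threshold* activities is excluded ("over"
    means a strict inequality).
    """
    if threshold < 0:
        raise UserError("threshold must be >= 0")
    if activities.empty:
        return []
    counts = activities.groupby("pid").size()
    return sorted(counts[counts > threshold].index)


@dataclass
class Violation:
    kind: str
    detail: str


def validate_harmony(tables: HarmonyTables) -> list[Violation]:
    """Check the schema invariants; violations are data, not exceptions."""
    out: list[Violation] = []

    def check_json(df: pd.DataFrame, id_col: str) -> None:
        dupes = df[id_col][df[id_col].duplicated()]
        for value in dupes:
            out.append(Violation("duplicate-id", f"{id_col}={value}"))
        for _, row in df.iterrows():
            try:
                parsed = json.loads(row["data"])
                if not isinstance(parsed, dict):
                    raise ValueError("not an object")
            except (ValueError, TypeError):
                out.append(Violation("bad-json", f"{id_col}={row[id_col]}"))

    check_json(tables.substances, "sid")
    check_json(tables.properties, "pid")

    sids = set(tables.substances["sid"])
    pids = set(tables.properties["pid"])
    for _, row in tables.activities.iterrows():
        if row["sid"] not in sids:
            out.append(Violation("unknown-sid", f"aid={row['aid']} sid={row['sid']}"))
        if row["pid"] not in pids:
            out.append(Violation("unknown-pid", f"aid={row['aid']} pid={row['pid']}"))
        has_binary = pd.notna(row["value_binary"])
        has_numeric = pd.notna(row["value_numeric"])
        exclusive = (
            (row["value_kind"] == "binary" and has_binary and not has_numeric)
            or (row["value_kind"] == "numeric" and has_numeric and not has_binary)
        )
        if not exclusive:
            out.append(Violation("value-kind", f"aid={row['aid']}"))
    return out


def write_harmony(tables: HarmonyTables, outdir) -> dict[str, str]:
    """Write the three tables as Parquet plus a CSV rejections report."""
    from pathlib import Path

    import pyarrow as pa
    import pyarrow.parquet as pq

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in (
        ("substances", tables.substances),
        ("properties", tables.properties),
        ("activities", tables.activities),
    ):
        path = outdir / f"{name}.parquet"
        pq.write_table(pa.Table.from_pandas(df, preserve_index=False), path)
        written[name] = str(path)
    rej = outdir / "rejections.csv"
    tables.rejections.to_csv(rej, index=False)
    written["rejections"] = str(rej)
    return written
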