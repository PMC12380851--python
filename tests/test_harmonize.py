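"""Harmonization: conservation, structure-keyed dedup, determinism."""

import json

import pandas as pd
import pytest

from brickyard import (
    Candidate,
    Rejection,
    SourceAdapter,
    UserError,
    count_activities_by_source,
    harmonize,
    major_properties,
    validate_harmony,
    write_harmony,
)
from brickyard.fixtures import ChemSpec, make_chem_sources
from brickyard.harmonize import HarmonyTables, canonical_json


class MiniAdapter(SourceAdapter):
    """Toy layout: inchi, prop, kind ('bin'/'num'), value."""

    def __init__(self, name):
        self.name = name

    def map_row(self, row):
        if row["kind"] == "bin":
            return Candidate(
                substance_meta={"inchi": row["inchi"]},
                property_key=row["prop"],
                property_meta={"prop": row["prop"]},
                value_kind="binary",
                value_binary=row["value"],
                inchi=row["inchi"],
            )
        if row["kind"] == "num":
            return Candidate(
                substance_meta={"inchi": row["inchi"]},
                property_key=row["prop"],
                property_meta={"prop": row["prop"]},
                value_kind="numeric",
                value_numeric=float(row["value"]),
                unit="uM",
                inchi=row["inchi"],
            )
        return Rejection("bad-kind")


def _mini(name, rows):
    return (MiniAdapter(name), pd.DataFrame(rows))


class TestHarmonize:
    def test_shared_inchi_collapses_to_one_sid(self):
        shared = "InChI=1S/CH4/h1H4"
        s1 = _mini("s1", [{"inchi": shared, "prop": "p1", "kind": "bin", "value": "positive"},
                          {"inchi": "InChI=1S/A", "prop": "p1", "kind": "bin", "value": "negative"}])
        s2 = _mini("s2", [{"inchi": shared, "prop": "q1", "kind": "num", "value": 3.5}])
        tables = harmonize([s1, s2])
        assert len(tables.substances) == 2  # shared + A
        shared_sids = tables.activities[tables.activities["inchi"] == shared]["sid"]
        assert shared_sids.nunique() == 1
        assert set(tables.activities["source"]) == {"s1", "s2"}

    def test_empty_source_contributes_nothing(self):
        s1 = _mini("s1", [{"inchi": "InChI=1S/A", "prop": "p", "kind": "bin", "value": "positive"}])
        empty = (MiniAdapter("s0"), pd.DataFrame(columns=["inchi", "prop", "kind", "value"]))
        tables = harmonize([s1, empty])
        assert len(tables.activities) == 1 and len(tables.substances) == 1

    def test_rerun_is_byte_identical(self):
        sources = make_chem_sources(ChemSpec(seed=5))
        t1 = harmonize(sources)
        t2 = harmonize(make_chem_sources(ChemSpec(seed=5)))
        assert t1.to_canonical_csv() == t2.to_canonical_csv()

    def test_ids_stable_when_a_source_is_added(self):
        base = make_chem_sources(ChemSpec(seed=6, rows=(20, 15), invalid_rows=(0, 0)))
        extended = make_chem_sources(ChemSpec(seed=6, rows=(20, 15, 10), invalid_rows=(0, 0, 0)))
        t_base = harmonize(base)
        t_ext = harmonize(extended)
        assert set(t_base.substances["sid"]) <= set(t_ext.substances["sid"])
        assert set(t_base.properties["pid"]) <= set(t_ext.properties["pid"])

    def test_conservation_per_source(self):
        spec = ChemSpec(seed=2, rows=(40, 30, 20), invalid_rows=(3, 2, 1))
        sources = make_chem_sources(spec)
        tables = harmonize(sources)
        for (adapter, df) in sources:
            n_act = (tables.activities["source"] == adapter.name).sum()
            n_rej = (tables.rejections["source"] == adapter.name).sum()
            assert n_act + n_rej == len(df)
        assert len(tables.rejections) == sum(spec.invalid_rows)

    def test_substances_equal_brute_force_structure_keys(self):
        sources = make_chem_sources(ChemSpec(seed=4))
        tables = harmonize(sources)
        keys = set()
        for adapter, df in sources:
            for row in df.to_dict(orient="records"):
                cand = adapter.map_row(row)
                if isinstance(cand, Rejection):
                    continue
                if cand.inchi:
                    keys.add(("inchi", cand.inchi))
                elif cand.smiles:
                    keys.add(("smiles", cand.smiles))
                else:
                    keys.add(("local", adapter.name, cand.local_substance_id))
        assert len(tables.substances) == len(keys)

    def test_adapter_contract_violation_names_source_and_row(self):
        class Broken(MiniAdapter):
            def map_row(self, row):
                return Candidate(
                    substance_meta={}, property_key="p", property_meta={},
                    value_kind="binary", value_binary="positive",
                    value_numeric=1.0, inchi="InChI=1S/X",
                )

        with pytest.raises(UserError, match="'broken', row 0"):
            harmonize([(Broken("broken"), pd.DataFrame([{"x": 1}]))])

    def test_metadata_is_canonical_json(self):
        sources = make_chem_sources(ChemSpec(seed=1))
        tables = harmonize(sources)
        for data in tables.substances["data"]:
            assert data == canonical_json(json.loads(data))


class TestSummaries:
    def test_empty_activities_empty_counts(self):
        empty = harmonize(
            [(MiniAdapter("s"), pd.DataFrame(columns=["inchi", "prop", "kind", "value"]))]
        )
        assert count_activities_by_source(empty.activities).empty
        assert major_properties(empty.activities) == []

    def test_planted_counts_5_7_11(self):
        def rows(n, tag):
            return [
                {"inchi": f"InChI=1S/{tag}{i}", "prop": "p", "kind": "bin", "value": "positive"}
                for i in range(n)
            ]

        tables = harmonize(
            [_mini("alpha", rows(5, "a")), _mini("beta", rows(7, "b")), _mini("gamma", rows(11, "c"))]
        )
        counts = count_activities_by_source(tables.activities)
        assert dict(zip(counts["source"], counts["n"])) == {
            "alpha": 5, "beta": 7, "gamma": 11,
        }
        assert counts["n"].sum() == len(tables.activities) == 23

    def test_major_properties_threshold_is_strict(self):
        # one property with exactly 1000 activities, one with 1001
        rows = []
        for i in range(1000):
            rows.append({"inchi": f"InChI=1S/x{i}", "prop": "exactly", "kind": "bin", "value": "positive"})
        for i in range(1001):
            rows.append({"inchi": f"InChI=1S/y{i}", "prop": "over", "kind": "bin", "value": "positive"})
        tables = harmonize([_mini("s", rows)])
        major = major_properties(tables.activities, threshold=1000)
        assert len(major) == 1
        meta = tables.properties.set_index("pid").loc[major[0], "data"]
        assert json.loads(meta) == {"prop": "over"}

    def test_major_properties_matches_group_by_oracle(self):
        sources = make_chem_sources(ChemSpec(seed=3, rows=(60, 50, 40), n_properties=3))
        tables = harmonize(sources)
        threshold = 20
        oracle = sorted(
            pid
            for pid, n in tables.activities.groupby("pid").size().items()
            if n > threshold
        )
        assert major_properties(tables.activities, threshold) == oracle


class TestValidate:
    def test_valid_fixture_has_no_violations(self):
        tables = harmonize(make_chem_sources(ChemSpec(seed=7)))
        assert validate_harmony(tables) == []

    def test_unknown_sid_is_one_referential_violation(self):
        tables = harmonize(make_chem_sources(ChemSpec(seed=7, rows=(5, 5), invalid_rows=(0, 0))))
        broken = HarmonyTables(
            substances=tables.substances.iloc[1:],
            properties=tables.properties,
            activities=tables.activities,
            rejections=tables.rejections,
        )
        missing_sid = tables.substances.iloc[0]["sid"]
        expected = (tables.activities["sid"] == missing_sid).sum()
        violations = [v for v in validate_harmony(broken) if v.kind == "unknown-sid"]
        assert len(violations) == expected > 0

    def test_both_value_kinds_is_exclusivity_violation(self):
        tables = harmonize(make_chem_sources(ChemSpec(seed=7, rows=(5, 5), invalid_rows=(0, 0))))
        acts = tables.activities.copy()
        acts.loc[0, "value_numeric"] = 1.0
        acts.loc[0, "value_binary"] = "positive"
        broken = HarmonyTables(tables.substances, tables.properties, acts, tables.rejections)
        assert sum(v.kind == "value-kind" for v in validate_harmony(broken)) == 1


def test_written_outputs_round_trip(tmp_path):
    tables = harmonize(make_chem_sources(ChemSpec(seed=9)))
    written = write_harmony(tables, tmp_path / "out")
    acts = pd.read_parquet(written["activities"])
    assert len(acts) == len(tables.activities)
    rej = pd.read_csv(written["rejections"])
    assert len(rej) == len(tables.rejections)
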