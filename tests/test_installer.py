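"""Install orchestration: ordering, idempotence, atomicity, coexistence."""

import json
from pathlib import Path

import pytest

from brickyard import BrickRef, CollisionError, Library, UserError
from brickyard import fixtures as fx
from brickyard.library import INSTALL_EVENTS
from brickyard.store import file_md5


def _tree(root: Path) -> dict[str, str]:
    """Relative path -> content md5 for every visible file (dotdirs excluded)."""
    out = {}
    for path in sorted(root.rglob("*")):
        rel = path.relative_to(root)
        if any(part.startswith(".") for part in rel.parts):
            continue
        if path.is_file():
            out[str(rel)] = file_md5(path)
    return out


class TestInstall:
    def test_chain_installs_in_dependency_order(self, library, chain_registry):
        executed = library.install("abrick")
        assert [r.name for r in executed] == ["cbrick", "bbrick", "abrick"]
        assert library.installed == set(chain_registry.refs.values())

    def test_second_install_is_noop(self, library):
        library.install("abrick")
        assert len(library.install("abrick")) == 0

    def test_shared_file_cached_once(self, library):
        library.install("abrick")
        # 4 asset records across 3 bricks, but the shared file is one object
        assert library.store.object_count == 3

    def test_reproducible_across_fresh_libraries(self, chain_registry, tmp_path):
        lib1 = Library(tmp_path / "lib1", chain_registry.registry, default_org="demo")
        lib2 = Library(tmp_path / "lib2", chain_registry.registry, default_org="demo")
        lib1.install("abrick")
        lib2.install("abrick")
        t1, t2 = _tree(lib1.root), _tree(lib2.root)
        assert t1 == t2 and len(t1) == 4

    def test_dry_run_executes_nothing(self, library):
        planned = library.install("abrick", dry_run=True)
        assert len(planned) == 3
        assert library.installed == set()

    def test_unknown_brick_leaves_library_empty(self, library):
        from brickyard import BrickNotFoundError

        with pytest.raises(BrickNotFoundError):
            library.install("missing-brick")
        assert library.installed == set()
        assert _tree(library.root) == {}


class TestAtomicity:
    @pytest.mark.parametrize("kill_event", INSTALL_EVENTS[:-1])
    def test_kill_at_each_step_leaves_no_partial_brick(
        self, chain_registry, tmp_path, kill_event
    ):
        """Interrupting any pre-commit step must not expose a partial brick."""

        class Kill(RuntimeError):
            pass

        seen = []

        def hook(event, ref):
            seen.append(event)
            if event == kill_event and ref.name == "bbrick":
                raise Kill(event)

        lib = Library(
            tmp_path / "lib", chain_registry.registry, default_org="demo", hook=hook
        )
        with pytest.raises(Kill):
            lib.install("abrick")
        # cbrick committed, bbrick/abrick must be invisible
        installed_names = {r.name for r in lib.installed}
        assert "bbrick" not in installed_names and "abrick" not in installed_names
        visible = _tree(lib.root)
        assert not any("bbrick" in p or "abrick" in p for p in visible)

        # a clean re-run completes using whatever was already cached
        reads_before = chain_registry.registry.object_reads
        lib2 = Library(tmp_path / "lib", chain_registry.registry, default_org="demo")
        executed = lib2.install("abrick")
        assert {r.name for r in lib2.installed} == {"cbrick", "bbrick", "abrick"}
        # cached objects are never re-fetched
        total_reads = chain_registry.registry.object_reads
        assert total_reads - reads_before <= 3
        assert total_reads <= 3  # 3 distinct objects overall, ever

    def test_backend_failure_mid_fetch_recovers(self, chain_registry, tmp_path):
        reg = chain_registry.registry
        reg.fail_after_reads = 2
        lib = Library(tmp_path / "lib", reg, default_org="demo")
        with pytest.raises(Exception):
            lib.install("abrick")
        reg.fail_after_reads = None
        lib.install("abrick")
        assert len(lib.installed) == 3
        assert reg.object_reads == 3  # nothing fetched twice


class TestCoexistence:
    def test_two_commits_two_paths_one_shared_object(self, tmp_path):
        spec = fx.RegistrySpec(
            seed=9,
            bricks=[
                fx.BrickSpec(
                    "data", key="v1",
                    assets=[fx.AssetSpec("assets/shared.bin", content_id="s")],
                ),
                fx.BrickSpec(
                    "data", key="v2",
                    assets=[
                        fx.AssetSpec("assets/shared.bin", content_id="s"),
                        fx.AssetSpec("assets/new.bin"),
                    ],
                ),
            ],
        )
        built = fx.make_local_registry(spec, tmp_path / "reg")
        lib = Library(tmp_path / "lib", built.registry, default_org="demo")
        v1, v2 = built.refs["v1"], built.refs["v2"]
        lib.install(v1)
        lib.install(v2)
        assert len(lib.installed) == 2
        dirs = sorted(p.name for p in (lib.root / "demo" / "data").iterdir())
        assert dirs == sorted({v1.commit[:5], v2.commit[:5]})
        assert lib.store.object_count == 2  # shared.bin counted once

    def test_prefix_collision_raises(self, library):
        """Distinct commits sharing a 5-char prefix must refuse to overlay."""
        fake = BrickRef("demo", "abrick", "abcde" + "0" * 27)
        clash = BrickRef("demo", "abrick", "abcde" + "f" * 27)
        receipt = library._receipt_path(fake)
        receipt.parent.mkdir(parents=True)
        receipt.write_text(json.dumps({
            "organization": "demo", "name": "abrick", "commit": fake.commit,
            "assets": [],
        }))
        with pytest.raises(CollisionError, match="abcde"):
            library._check_collision(clash)


class TestWorkingBrick:
    def test_init_creates_empty_dependency_file(self, library, tmp_path):
        work = tmp_path / "work"
        work.mkdir()
        wb = library.init(work)
        assert wb.deps_path.read_text() == ""
        assert len(wb.dependencies()) == 0

    def test_reinit_refuses_to_clobber(self, library, tmp_path):
        work = tmp_path / "work"
        work.mkdir()
        library.init(work)
        with pytest.raises(UserError, match="already initialized"):
            library.init(work)

    def test_add_pins_installs_and_is_idempotent(self, library, tmp_path):
        work = tmp_path / "work"
        work.mkdir()
        library.init(work)
        deps = library.add(work, "bbrick")
        assert [d.name for d in deps] == ["bbrick"]
        assert deps.entries[0].pinned
        assert {r.name for r in library.installed} == {"bbrick", "cbrick"}
        again = library.add(work, "bbrick")
        assert len(again) == 1

    def test_add_unknown_leaves_file_unchanged(self, library, tmp_path):
        from brickyard import BrickNotFoundError

        work = tmp_path / "work"
        work.mkdir()
        wb = library.init(work)
        with pytest.raises(BrickNotFoundError):
            library.add(work, "ghost")
        assert wb.deps_path.read_text() == ""

    def test_pull_installs_only_missing(self, library, tmp_path, chain_registry):
        work = tmp_path / "work"
        work.mkdir()
        library.init(work)
        library.add(work, "cbrick")
        library.add(work, "abrick")
        # wipe and re-pull: bbrick+abrick remain from add; fresh library pulls all
        lib2 = Library(
            tmp_path / "lib2", chain_registry.registry, default_org="demo"
        )
        lib2.install("cbrick")
        executed = lib2.pull(work)
        assert {r.name for r in executed} == {"bbrick", "abrick"}
        assert len(lib2.pull(work)) == 0


class TestInspection:
    def test_assets_paths_exist_and_match_manifest(self, library, chain_registry):
        library.install("bbrick")
        paths = library.assets("bbrick")
        assert set(paths) == {"b", "shared"}
        manifest, _ = chain_registry.registry.fetch_metadata(
            chain_registry.refs["bbrick"]
        )
        by_stem = {Path(a.relative_path).stem: a.md5 for a in manifest.assets}
        for stem, path in paths.items():
            assert path.is_file()
            assert file_md5(path) == by_stem[stem]

    def test_assets_of_uninstalled_brick_errors(self, library):
        with pytest.raises(UserError, match="install"):
            library.assets("abrick")

    def test_status_reflects_dedup_and_gc(self, library):
        st = library.status()
        assert st.installed == [] and st.object_count == 0
        library.install("abrick")
        st = library.status()
        assert len(st.installed) == 3
        assert st.object_count == 3  # 4 asset records, 3 distinct objects
        assert st.orphans == []
        # drop a receipt -> its unshared objects become orphans, gc removes them
        victim = next(r for r in library.installed if r.name == "cbrick")
        library._receipt_path(victim).unlink()
        orphans = library.status().orphans
        assert len(orphans) == 1
        assert library.gc() == 1
        assert library.status().orphans == []
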