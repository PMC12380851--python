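import pytest

from brickyard import Library
from brickyard import fixtures as fx


@pytest.fixture
def chain_spec() -> fx.RegistrySpec:
    """Three bricks a -> b -> c with one asset shared between a and b."""
    return fx.RegistrySpec(
        seed=7,
        bricks=[
            fx.BrickSpec("cbrick", assets=[fx.AssetSpec("assets/c.txt", size=128)]),
            fx.BrickSpec(
                "bbrick",
                assets=[
                    fx.AssetSpec("assets/b.txt", size=200),
                    fx.AssetSpec("assets/shared.txt", content_id="shared", size=300),
                ],
                deps=["cbrick"],
            ),
            fx.BrickSpec(
                "abrick",
                assets=[fx.AssetSpec("assets/shared.txt", content_id="shared", size=300)],
                deps=["bbrick"],
            ),
        ],
    )


@pytest.fixture
def chain_registry(chain_spec, tmp_path):
    return fx.make_local_registry(chain_spec, tmp_path / "registry", instrumented=True)


@pytest.fixture
def library(chain_registry, tmp_path):
    return Library(tmp_path / "library", chain_registry.registry, default_org="demo")
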