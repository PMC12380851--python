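"""Install a brick with its dependency chain and inspect the library.

Builds a three-brick demo registry (abrick -> bbrick -> cbrick, with one
file shared between abrick and bbrick), installs the top brick, and shows
the install order, cache deduplication, and asset paths.
"""

import tempfile
from pathlib import Path

from brickyard import Library
from brickyard import fixtures as fx

work = Path(tempfile.mkdtemp(prefix="brickyard-demo-"))

spec = fx.RegistrySpec(
    seed=0,
    bricks=[
        fx.BrickSpec("cbrick", assets=[fx.AssetSpec("assets/c.txt")]),
        fx.BrickSpec(
            "bbrick",
            assets=[
                fx.AssetSpec("assets/b.txt"),
                fx.AssetSpec("assets/shared.txt", content_id="shared"),
            ],
            deps=["cbrick"],
        ),
        fx.BrickSpec(
            "abrick",
            assets=[fx.AssetSpec("assets/shared.txt", content_id="shared")],
            deps=["bbrick"],
        ),
    ],
)
built = fx.make_local_registry(spec, work / "registry")
library = Library(work / "library", built.registry, default_org="demo")

executed = library.install("abrick")
print("install order:", [ref.slug for ref in executed])
# dependencies first: cbrick, then bbrick, then abrick

status = library.status()
print("installed bricks:", len(status.installed))
print("cache objects:", status.object_count)
# 4 asset records across 3 bricks but only 3 cache objects:
# the shared file is stored once and hardlinked into both bricks

print("re-install executes:", len(library.install("abrick")), "bricks (no-op)")

for name, path in library.assets("bbrick").items():
    print(f"asset {name!r} -> {path}")
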