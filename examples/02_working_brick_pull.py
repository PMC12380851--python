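"""Develop a brick that depends on others: init, add, pull.

A working directory gets `.bb/dependencies.txt` scaffolding; `add` pins a
brick (resolving the registry's latest commit) and installs it; a second
developer's `pull` installs exactly the missing bricks, so everyone works
against the same pinned data versions.
"""

import tempfile
from pathlib import Path

from brickyard import Library
from brickyard import fixtures as fx

work = Path(tempfile.mkdtemp(prefix="brickyard-demo-"))
spec = fx.RegistrySpec(
    seed=0,
    bricks=[
        fx.BrickSpec("tox-data", assets=[fx.AssetSpec("assets/tox.csv")]),
        fx.BrickSpec("gene-map", assets=[fx.AssetSpec("assets/map.tsv")]),
    ],
)
built = fx.make_local_registry(spec, work / "registry")

dev1 = Library(work / "lib-dev1", built.registry, default_org="demo")
project = work / "my-harmonized-brick"
project.mkdir()
dev1.init(project)
dev1.add(project, "tox-data")
dev1.add(project, "gene-map")
print("dependency file:")
print((project / ".bb" / "dependencies.txt").read_text())
# each line is `<locator> <commit>` — an exact, reproducible pin

dev2 = Library(work / "lib-dev2", built.registry, default_org="demo")
pulled = dev2.pull(project)
print("second developer pulled:", [r.name for r in pulled])
print("second pull installs:", len(dev2.pull(project)), "bricks (all present)")
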