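"""Detect cache corruption with verify() and restore it by reinstalling.

Flips one byte in one cached object: verify() flags exactly that key, and
repair() drops the bad object, discards the affected brick, and reinstalls
it from the registry.
"""

import tempfile
from pathlib import Path

from brickyard import Library
from brickyard import fixtures as fx

work = Path(tempfile.mkdtemp(prefix="brickyard-demo-"))
spec = fx.RegistrySpec(
    seed=0,
    bricks=[fx.BrickSpec("refdata", assets=[
        fx.AssetSpec("assets/table.bin", size=1024),
        fx.AssetSpec("assets/index.bin", size=256),
    ])],
)
built = fx.make_local_registry(spec, work / "registry")
library = Library(work / "library", built.registry, default_org="demo", link_mode="copy")
library.install("refdata")

victim = sorted(library.store.keys())[0]
path = library.store.object_path(victim)
data = bytearray(path.read_bytes())
data[0] ^= 0x01
path.write_bytes(bytes(data))
print(f"flipped one byte in cached object {victim}")

report = library.verify()
print(f"verify scanned {report.object_count} objects, corrupt: {report.corrupt}")

repaired = library.repair(report)
print(f"repair() replaced {repaired} object(s)")
print("verify after repair, corrupt:", library.verify().corrupt)
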