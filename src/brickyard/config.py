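"""User configuration: library path, registry location, token, default org.

Stored as TOML at ``$BRICKYARD_CONFIG`` or ``~/.config/brickyard/config.toml``.
The token gates nothing locally but auth-marked backends require it to be
nonempty (registration, not a paywall).
"""

from __future__ import annotations

import os
import tomllib
from dataclasses import dataclass
from pathlib import Path

from .errors import UserError

ENV_VAR = "BRICKYARD_CONFIG"


def default_config_path() -> Path:
    env = os.environ.get(ENV_VAR)
    if env:
        return Path(env)
    return Path.home() / ".config" / "brickyard" / "config.toml"


@dataclass
class Config:
    library: Path
    registry: str
    token: str | None = None
    default_org: str = "local"

    def to_toml(self) -> str:
        lines = [
            f'BBLIB = "{self.library}"',
            f'REGISTRY = "{self.registry}"',
            f'DEFAULT_ORG = "{self.default_org}"',
        ]
        if self.token:
            lines.append(f'TOKEN = "{self.token}"')
        return "".join(line + "\n" for line in lines)


def load_config(path: Path | None = None) -> Config:
    path = path or default_config_path()
    if not path.is_file():
        raise UserError(
            f"no config at {path}; run 'brickyard configure' first"
        )
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    try:
        return Config(
            library=Path(data["BBLIB"]),
            registry=str(data["REGISTRY"]),
            token=data.get("TOKEN"),
            default_org=data.get("DEFAULT_ORG", "local"),
        )
    except KeyError as exc:
        raise UserError(f"config {path} is missing key {exc}") from exc


def save_config(cfg: Config, path: Path | None = None) -> Path:
    path = path or default_config_path()
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(cfg.to_toml(), encoding="utf-8")
    return path
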