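"""Run configuration, deterministic seed fan-out and provenance records."""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "stage_seed", "write_provenance"]

MAX_SEED = 2**31 - 1


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed from one global seed by stable hashing."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) % MAX_SEED


@dataclass
class RunConfig:
    """Global run options shared by all CLI subcommands."""

    seed: int = 0
    log_level: str = "INFO"
    preset: str | None = None
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def write_provenance(out_path: str | Path, command: str, config: dict, seed: int) -> None:
    """Record what produced an artifact next to the artifact itself."""
    import numpy
    from . import __version__

    record = {
        "command": command,
        "config": {k: str(v) for k, v in config.items()},
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "seed": seed,
        "versions": {"organaxis": __version__, "numpy": numpy.__version__},
    }
    path = Path(str(out_path) + ".provenance.json")
    path.write_text(json.dumps(record, indent=1))
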