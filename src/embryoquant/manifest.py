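"""Run manifests: configuration hash, seed, stages, timings."""

from __future__ import annotations

import hashlib
import json
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .config import SimConfig


def config_hash(config: SimConfig) -> str:
    canonical = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str = __version__
    stages: list = field(default_factory=list)

    @classmethod
    def create(cls, config: SimConfig, seed: int) -> "RunManifest":
        return cls(config_hash=config_hash(config), seed=seed)

    @contextmanager
    def stage(self, name: str, inputs: list[str] | None = None,
              outputs: list[str] | None = None):
        t0 = time.perf_counter()
        try:
            yield
        finally:
            self.stages.append({
                "name": name,
                "inputs": inputs or [],
                "outputs": outputs or [],
                "wall_time_s": round(time.perf_counter() - t0, 4),
            })

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
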