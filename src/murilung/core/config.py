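"""Run configuration, seeded random streams, and stage logging.

A single integer seed drives every random stage.  Stage-specific generators
are spawned deterministically by name so that re-running one stage with the
same config reproduces it bit-for-bit regardless of the other stages.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

__all__ = ["RunConfig", "make_rng", "stage_rng", "get_logger", "log_params"]


def make_rng(seed: int) -> np.random.Generator:
    """A fresh PCG64 generator for an integer seed."""
    return np.random.default_rng(int(seed))


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from (seed, stage name)."""
    digest = hashlib.sha256(f"{int(seed)}:{stage}".encode()).digest()
    child = int.from_bytes(digest[:4], "little") % (2**31)
    return np.random.default_rng([int(seed) % (2**31), child])


@dataclass
class RunConfig:
    """Seed plus per-stage parameter overrides, loadable from YAML."""

    seed: int = 0
    paths: dict[str, str] = field(default_factory=dict)
    params: dict[str, dict[str, Any]] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            seed=int(raw.get("seed", 0)),
            paths=dict(raw.get("paths", {})),
            params={k: dict(v) for k, v in raw.get("params", {}).items()},
        )

    def stage(self, name: str, **defaults) -> dict[str, Any]:
        """Defaults for a stage, overridden by any config entries."""
        merged = dict(defaults)
        merged.update(self.params.get(name, {}))
        return merged

    def rng(self, stage: str) -> np.random.Generator:
        return stage_rng(self.seed, stage)


def get_logger(stage: str) -> logging.Logger:
    logger = logging.getLogger(f"murilung.{stage}")
    if not logger.handlers and not logging.getLogger().handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


def log_params(logger: logging.Logger, **params) -> None:
    """Echo stage parameters into the log as a reproducibility record."""
    logger.info("parameters: %s", {k: params[k] for k in sorted(params)})
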