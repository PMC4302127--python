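"""Declarative run configuration, seed substreams and structured logging.

A run is reproducible from (config, seed) alone: one global seed spawns
named per-stage substreams so each pipeline stage can be rerun
independently with identical random numbers.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

__all__ = ["RunConfig", "load_config", "stage_rng", "config_hash", "kv_log"]

log = logging.getLogger("ecmopk")

_STAGES = {
    "generate": 1,
    "fit": 2,
    "search": 3,
    "bootstrap": 4,
    "dose_sim": 5,
    "recovery": 6,
}

DEFAULTS: dict[str, Any] = {
    "seed": 20140565,
    "study": {
        "loq": 1.0,
        "bsv": True,
        "residual": True,
    },
    "model": {
        "structure": "final",      # "final" (RRT/CrCL branches) or "base"
        "max_iter": 300,
    },
    "dose_sim": {
        "n": 1000,
        "doses_mg": [500, 1000, 2000],
        "crcls": [20, 50, 80, 120, 180],
        "at": "steady_state",      # or a 1-based dose index
        "include_residual": False,
        "theta_cl": 5.1,
        "theta_crcl": 1.89,
        "theta_vc": 18.7,
        "theta_vp": 13.2,
        "theta_q": 21.0,
        "bsv_cv_cl": 51.6,
        "bsv_cv_vc": 45.8,
        "bsv_cv_vp": 28.7,
    },
    "bootstrap": {
        "n": 1000,
    },
}

_REQUIRED_KEYS = ("seed", "study", "model", "dose_sim", "bootstrap")


def _merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


@dataclass(frozen=True)
class RunConfig:
    data: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULTS)))

    def __getitem__(self, key: str) -> Any:
        return self.data[key]

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    def hash(self) -> str:
        return config_hash(self.data)


def config_hash(data: Mapping) -> str:
    canon = json.dumps(data, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def load_config(path: str | Path | None = None) -> RunConfig:
    """Defaults overlaid with a YAML file; missing top-level keys error."""
    data = json.loads(json.dumps(DEFAULTS))
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, Mapping):
            raise ValueError(f"{path}: config must be a mapping")
        unknown = [k for k in raw if k not in DEFAULTS]
        if unknown:
            raise ValueError(f"{path}: unknown config keys {unknown}")
        data = _merge(data, raw)
    missing = [k for k in _REQUIRED_KEYS if k not in data]
    if missing:
        raise ValueError(f"config missing required keys: {missing}")
    return RunConfig(data)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Named, independent substream of the global seed."""
    if stage not in _STAGES:
        raise KeyError(f"unknown stage {stage!r}; known: {sorted(_STAGES)}")
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STAGES[stage],))
    )


def kv_log(event: str, **fields: Any) -> None:
    """Structured key-value log line."""
    parts = " ".join(f"{k}={v}" for k, v in fields.items())
    log.info("%s %s", event, parts)
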