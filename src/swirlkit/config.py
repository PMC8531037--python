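"""Run configuration: YAML loading, validation, hashing and file outputs.

The configuration is a strict schema (unknown keys are rejected) with
documented defaults; every output directory gets a JSON manifest recording
the seed, the config hash and library versions, which is sufficient to
reproduce a run bit-for-bit in single-threaded mode.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from .kinematics import EnvConfig, LeaderPath
from .reinforce import TrainConfig
from .rewards import RewardConstants

__all__ = ["RunConfig", "load_config", "dump_config", "config_hash", "write_outputs"]


@dataclass
class LeaderConfig:
    kind: str = "circle"
    speed: float = 0.5
    radius: float = 2.0
    a: float = 2.0
    b: float = 1.0
    pitch: float = 0.15
    turns: float = 6.0
    vertices: Optional[list] = None

    def build(self) -> LeaderPath:
        params: dict[str, Any] = {}
        if self.kind == "circle":
            params["radius"] = self.radius
        elif self.kind == "ellipse":
            params.update(a=self.a, b=self.b)
        elif self.kind == "eight":
            params["a"] = self.a
        elif self.kind == "spiral":
            params.update(pitch=self.pitch, turns=self.turns)
        elif self.kind == "triangle" and self.vertices is not None:
            params["vertices"] = self.vertices
        return LeaderPath(kind=self.kind, speed=self.speed, **params)


@dataclass
class ForceConfig:
    f0: float = 0.0
    beta: float = 1.0
    modulation_period: int = 50


@dataclass
class HydroConfig:
    a: float = 1.0
    eta_fluid: float = 1.0 / (6.0 * math.pi)
    v_lead: list = field(default_factory=lambda: [1.0, 0.0])


@dataclass
class RunConfig:
    env: EnvConfig = field(default_factory=EnvConfig)
    reward: RewardConstants = field(default_factory=RewardConstants)
    training: TrainConfig = field(default_factory=TrainConfig)
    leader: LeaderConfig = field(default_factory=LeaderConfig)
    force: ForceConfig = field(default_factory=ForceConfig)
    hydro: HydroConfig = field(default_factory=HydroConfig)
    seed: int = 0
    shared_policy: bool = False
    hidden: int = 128


_SECTIONS = {
    "env": EnvConfig,
    "reward": RewardConstants,
    "training": TrainConfig,
    "leader": LeaderConfig,
    "force": ForceConfig,
    "hydro": HydroConfig,
}


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown key(s) in '{section}': {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid '{section}' configuration: {exc}") from exc


def load_config(path) -> RunConfig:
    """Parse and validate a YAML config file; defaults fill missing keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    top_known = set(_SECTIONS) | {"seed", "shared_policy", "hidden"}
    unknown = set(raw) - top_known
    if unknown:
        raise ValueError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for name, cls in _SECTIONS.items():
        data = raw.get(name, {})
        if not isinstance(data, dict):
            raise ValueError(f"section '{name}' must be a mapping")
        kwargs[name] = _build_section(cls, data, name)
    cfg = RunConfig(**kwargs)
    cfg.seed = int(raw.get("seed", 0))
    cfg.shared_policy = bool(raw.get("shared_policy", False))
    cfg.hidden = int(raw.get("hidden", 128))
    # the env seed mirrors the top-level one unless explicitly set
    if "env" not in raw or "seed" not in raw.get("env", {}):
        cfg.env.seed = cfg.seed
    if "training" not in raw or "seed" not in raw.get("training", {}):
        cfg.training.seed = cfg.seed
    return cfg


def _to_plain(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def dump_config(cfg: RunConfig) -> str:
    doc = _to_plain(asdict(cfg))
    return yaml.safe_dump(doc, sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(dump_config(cfg).encode()).hexdigest()[:16]


def write_outputs(
    out_dir,
    cfg: Optional[RunConfig] = None,
    trajectories: Optional[np.ndarray] = None,
    metrics: Optional[pd.DataFrame] = None,
    tables: Optional[dict[str, pd.DataFrame]] = None,
    params_docs: Optional[dict[str, Any]] = None,
    extra_manifest: Optional[dict] = None,
) -> dict[str, Path]:
    """Write the standard artifact set and a JSON manifest; returns paths.

    ``trajectories`` has shape (T, N, 6): columns (x, y, vx, vy, fx, fy)
    per agent per step, emitted as a long-format CSV.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if trajectories is not None:
        T, N, _ = trajectories.shape
        t_idx = np.repeat(np.arange(T), N)
        a_idx = np.tile(np.arange(N), T)
        flat = trajectories.reshape(T * N, 6)
        df = pd.DataFrame(
            {
                "t": t_idx,
                "agent_id": a_idx,
                "x": flat[:, 0],
                "y": flat[:, 1],
                "vx": flat[:, 2],
                "vy": flat[:, 3],
                "fx": flat[:, 4],
                "fy": flat[:, 5],
            }
        )
        path = out / "trajectories.csv"
        df.to_csv(path, index=False)
        written["trajectories"] = path

    if metrics is not None:
        path = out / "metrics.csv"
        metrics.to_csv(path, index=False)
        written["metrics"] = path

    for name, df in (tables or {}).items():
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        written[name] = path

    for name, doc in (params_docs or {}).items():
        path = out / f"{name}.json"
        with open(path, "w") as fh:
            json.dump(_to_plain(doc), fh)
        written[name] = path

    manifest = {
        "seed": cfg.seed if cfg is not None else None,
        "config_hash": config_hash(cfg) if cfg is not None else None,
        "config": dump_config(cfg) if cfg is not None else None,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    manifest.update(extra_manifest or {})
    path = out / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    written["manifest"] = path
    return written
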