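"""Run configuration: explicit defaults, serialization and hashing.

Every default that matters to reproducibility is materialized into the
serialized config (no hidden constants), and the SHA-256 hash of the
canonical JSON form is stamped into every output file.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .controller import ControllerParams
from .ga import GAConfig
from .vte import DEFAULT_THETA
from .world import MazeConfig, RobotPose

__all__ = ["RunConfig", "config_hash", "load_config", "save_array"]


def _default_maze() -> dict:
    cfg = MazeConfig()
    d = asdict(cfg)
    d["start_pose"] = [cfg.start_pose.x, cfg.start_pose.y, cfg.start_pose.heading]
    return d


def _default_controller() -> dict:
    return ControllerParams.uniform(eta=0.1, zeta=0.01, delta=10).to_dict()


def _default_ga() -> dict:
    return asdict(GAConfig())


def _default_analysis() -> dict:
    return {
        "vte_theta": DEFAULT_THETA,
        "vte_rule": "hysteresis",
        "mle_m": 5,
        "mle_J": 1,
        "mle_fit_len": 10,
        "grid_lateral": 7,
        "grid_longitudinal": 40,
    }


@dataclass
class RunConfig:
    """Top-level configuration for the CLI and pipeline."""

    maze: dict = field(default_factory=_default_maze)
    controller: dict = field(default_factory=_default_controller)
    ga: dict = field(default_factory=_default_ga)
    analysis: dict = field(default_factory=_default_analysis)
    topology: str = "full"
    n_trials: int = 100
    seed: int = 0
    out_dir: str = "vtemaze_out"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        base = cls()
        for section in ("maze", "controller", "ga", "analysis"):
            if section in d:
                getattr(base, section).update(d[section])
        if "maze" in d and "start_pose" not in d["maze"]:
            # geometry overridden: recompute (and re-materialize) the
            # default start pose instead of inheriting the stock maze's
            geom = dict(base.maze)
            geom.pop("start_pose", None)
            cfg = MazeConfig(**geom)
            base.maze["start_pose"] = [cfg.start_pose.x, cfg.start_pose.y,
                                       cfg.start_pose.heading]
        for key in ("topology", "n_trials", "seed", "out_dir"):
            if key in d:
                setattr(base, key, d[key])
        return base

    def maze_config(self) -> MazeConfig:
        d = dict(self.maze)
        sp = d.pop("start_pose", None)
        cfg = MazeConfig(**d) if sp is None else MazeConfig(
            **d, start_pose=RobotPose(*sp))
        return cfg

    def controller_params(self) -> ControllerParams:
        return ControllerParams.from_dict(self.controller)

    def ga_config(self) -> GAConfig:
        d = dict(self.ga)
        d.setdefault("seed", self.seed)
        return GAConfig(**d)

    def hash(self) -> str:
        return config_hash(self.to_dict())


def config_hash(d: dict) -> str:
    """SHA-256 of the canonical (sorted, compact) JSON form."""
    canon = json.dumps(d, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load a JSON or YAML config file (flat sections, documented defaults)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a JSON superset
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return RunConfig.from_dict(data)


def save_array(arr: np.ndarray, path: str | Path, *, meta: dict | None = None) -> None:
    """Write a dense array as flat little-endian float64 + JSON sidecar header."""
    path = Path(path)
    arr = np.asarray(arr, dtype="<f8")
    arr.tofile(path)
    header = {"shape": list(arr.shape), "dtype": "<f8", "order": "C"}
    if meta:
        header.update(meta)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(header, indent=1))
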