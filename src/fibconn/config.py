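"""Run configuration: a fully serializable description of one pipeline run.

A run is reproducible from (RunConfig, package version): every random draw
derives from the single seed, and the config hash is recorded in the run
manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .signals import ConnectivityGroundTruth, GaussianBump, default_truth

__all__ = ["EdgeSpec", "RunConfig", "load_config", "truth_from_config"]


@dataclass(frozen=True)
class EdgeSpec:
    """One LSBQ-modulated directed edge of the simulation ground truth."""

    from_roi: str
    to_roi: str
    baseline: float = 0.0
    height: float = 0.0
    center: float = 10.0
    width: float = 1.5


@dataclass
class RunConfig:
    seed: int = 0
    n_participants: int = 28
    # resting recordings
    duration_s: float = 300.0
    fs: float = 128.0
    innovation_sd_uv: float = 10.0
    conditions: tuple = ("pre", "post")
    # None -> the default ground truth for each condition; else explicit edges
    edges: dict | None = None  # condition -> list[EdgeSpec-like dict]
    # preprocessing
    seg_s: float = 10.0
    highpass_hz: float = 0.1
    # connectivity
    order_policy: str | int = "bic"
    max_order: int = 20
    # model
    k: int = 15
    penalty: float = 0.02
    re_penalty: float = 1.0
    fdr_q: float = 0.05
    test_method: str = "bootstrap"
    n_boot: int = 2000
    # behaviour
    include_behavior: bool = True
    out_dir: str = "fibconn_run"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conditions"] = list(self.conditions)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Read a YAML run configuration; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    valid = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    if isinstance(cfg.conditions, list):
        cfg.conditions = tuple(cfg.conditions)
    return cfg


def truth_from_config(cfg: RunConfig, condition: str) -> ConnectivityGroundTruth:
    """Materialize the ground truth for one condition."""
    if cfg.edges is None:
        truth = default_truth(condition)
        truth.innovation_sd_uv = cfg.innovation_sd_uv
        return truth
    mods = {}
    for e in cfg.edges.get(condition, []):
        spec = EdgeSpec(**e) if isinstance(e, dict) else e
        mods[(spec.from_roi, spec.to_roi)] = GaussianBump(
            baseline=spec.baseline,
            height=spec.height,
            center=spec.center,
            width=spec.width,
        )
    return ConnectivityGroundTruth(
        edge_modulators=mods,
        condition=condition,
        innovation_sd_uv=cfg.innovation_sd_uv,
    )
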