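"""Experiment configuration: schema, validation, hashing.

A single YAML file drives the whole pipeline. Unknown fields are
rejected with the offending names; omitted sections fall back to the
shipped defaults (model, task table, perturbation ranges).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = ["ExperimentConfig", "UQSettings", "MLSettings",
           "SensitivitySettings", "load_config", "config_hash"]


class UQSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    grf_noise_level: float = 0.03
    bootstrap_B: int = 200
    baseline_task: str = "quiet_stance"


class SensitivitySettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    lhs_n: int = 200
    oat_levels: int = 3
    outcome: str = "one_rm"            # 'one_rm' | task name
    run_convergence: bool = False


class MLSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    families: list[str] = Field(default_factory=lambda: ["random_forest",
                                                         "ann"])
    budget: int = 200
    tuning: str = "random"
    folds: int = 5
    target_noise: float = 0.10
    split_ratios: tuple[float, float, float] = (0.70, 0.15, 0.15)
    pca_variance: float | None = None

    @field_validator("tuning")
    @classmethod
    def _tuning(cls, v):
        if v not in ("random", "grid"):
            raise ValueError("tuning must be 'random' or 'grid'")
        return v


class ExperimentConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    model_file: str | None = None      # None -> shipped default
    tasks_file: str | None = None
    ranges_file: str | None = None
    replicates: int | None = None      # override per-task counts
    load_fraction: float = 0.85        # strength tasks' default load
    seed: int = 2024
    out_dir: str = "results"
    write_traces: bool = False
    uq: UQSettings = Field(default_factory=UQSettings)
    sensitivity: SensitivitySettings = Field(
        default_factory=SensitivitySettings)
    ml: MLSettings = Field(default_factory=MLSettings)

    def resolve_paths(self, root: Path) -> None:
        for name in ("model_file", "tasks_file", "ranges_file"):
            v = getattr(self, name)
            if v is not None:
                p = (root / v).resolve() if not Path(v).is_absolute() else Path(v)
                if not p.exists():
                    raise FileNotFoundError(f"{name}: {p} does not exist")
                setattr(self, name, str(p))


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = ExperimentConfig(**raw)
    cfg.resolve_paths(Path(path).parent)
    return cfg


def config_hash(cfg: ExperimentConfig) -> str:
    payload = json.dumps(cfg.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
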