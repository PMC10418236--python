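"""Declarative run configuration for end-to-end pipeline runs.

All analysis constants live here once, as defaults (FWER α = 0.05, auROC
threshold θ = 0.75, 5-fold CV, 10,000 shuffles, k = 15 subsampled neurons,
1,000 PR repeats, 2,500-frame baseline window); stage code never hard-codes
them.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, ValidationError


class ParadigmConfig(BaseModel):
    name: str = "six_odor"
    n_blocks: int = Field(30, ge=1)
    days: list[int] = [1, 2, 3, 4, 5, 6]


class PopulationBlock(BaseModel):
    region: str = "VP"
    n_neurons: int = Field(130, ge=1)
    preset: str = "vp_like"           # vp_like / ot_like / identity_only / custom
    class_fractions: dict[str, float] | None = None


class AnalysisConfig(BaseModel):
    alpha: float = Field(0.05, gt=0, lt=1)
    auroc_threshold: float = Field(0.75, gt=0.5, lt=1)
    k_folds: int = Field(5, ge=2)
    n_shuffles: int = Field(10000, ge=100)
    k_subsample: int = Field(15, ge=2)
    n_pr_repeats: int = Field(1000, ge=1)
    baseline_window_frames: int = Field(2500, ge=2)
    baseline_stride_frames: int = Field(500, ge=1)
    pre_s: float = 2.0
    post_s: float = 5.0


class RunConfig(BaseModel):
    seed: int = Field(..., ge=0)
    frame_rate_hz: float = Field(5.0, gt=0)
    paradigm: ParadigmConfig = ParadigmConfig()
    populations: list[PopulationBlock] = [PopulationBlock()]
    analysis: AnalysisConfig = AnalysisConfig()
    output_dir: str = "out"


def load_config(path: str | Path) -> RunConfig:
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    return RunConfig(**data)


def validate_config(path: str | Path) -> list[str]:
    """Schema validation only; returns a list of error strings (empty = ok)."""
    try:
        with open(path) as f:
            data = yaml.safe_load(f) or {}
    except (OSError, yaml.YAMLError) as e:
        return [str(e)]
    try:
        RunConfig(**data)
    except ValidationError as e:
        return [f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
                for err in e.errors()]
    return []
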