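"""Run configuration: YAML schema, validation, and seed derivation.

A single master seed deterministically derives one substream seed per
pipeline stage, so partial re-runs reproduce exactly.  Unknown keys are
rejected so typos fail loudly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .detect import ThresholdSpec
from .synthetic import SynthCalciumSpec, SynthCrzSpec, SynthPixelSpec
from .tdm import CnParams, CSMParams, TDMParams

__all__ = ["RunConfig", "validate_config", "stage_seed", "STAGES"]

STAGES = (
    "generate",
    "quantify",
    "detect",
    "analyze",
    "simulate_tdm",
    "simulate_csm",
    "fit_pulses",
    "periodicity",
)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeneratorConfig(_Strict):
    n_cells: int = Field(20, ge=1)
    duration_sec: float = Field(3600.0, gt=0)
    calcium: dict[str, Any] = Field(default_factory=dict)
    crz1: dict[str, Any] = Field(default_factory=dict)
    pixels: dict[str, Any] = Field(default_factory=dict)


class ThresholdConfig(_Strict):
    ca_height: float = Field(0.09, gt=0)
    crz1_height: float = Field(0.30, gt=0)
    crz1_prominence: float = Field(0.15, gt=0)
    min_distance_sec: float = Field(60.0, gt=0)
    ca_quantile: float = Field(0.995, gt=0, lt=1)
    crz1_quantile: float = Field(0.95, gt=0, lt=1)
    sg_window: int = Field(5, ge=3)
    sg_order: int = Field(2, ge=1)
    overshoot_window_sec: float = Field(300.0, gt=0)

    def to_spec(self) -> ThresholdSpec:
        return ThresholdSpec(**self.model_dump())


class CnConfig(_Strict):
    Cn_base: float = Field(0.002, ge=0)
    D: float = Field(0.008, gt=0, le=1)
    A: float = Field(0.03, ge=0)

    def to_params(self) -> CnParams:
        return CnParams(**self.model_dump())


class TdmConfig(_Strict):
    # Provenance of the numeric defaults: fitted-by-us to the observed
    # calcineurin relaxation (~5 min) and inter-pulse spacing (~3 min).
    cn: CnConfig = Field(default_factory=CnConfig)
    n_molecules: int = Field(500, ge=1)
    k_in: int = Field(60, ge=1)
    p_in: float = Field(0.8, gt=0, le=1)
    k_out: int = Field(60, ge=1)
    p_out: float = Field(0.8, gt=0, le=1)
    q_dephos: float = Field(0.25, ge=0, le=1)
    p_phos_nuc: float = Field(0.02, gt=0, le=1)
    signal_gain: float = Field(2.0, gt=0)
    dt_model: float = Field(1.0, gt=0)

    def to_params(self, seed: int = 0) -> TDMParams:
        d = self.model_dump()
        d["cn"] = self.cn.to_params()
        return TDMParams(**d, seed=seed)


class CsmConfig(_Strict):
    cn: CnConfig = Field(default_factory=lambda: CnConfig(Cn_base=0.002, D=0.05, A=0.03))
    hill_n: float = Field(50.0, ge=1)
    K: float = Field(0.3, gt=0)
    amplitude: float = Field(1.2, ge=0)
    period_sec: float = Field(300.0, gt=0)
    decay_tau: float = Field(500.0, gt=0)
    start_sec: float = Field(120.0, ge=0)
    dt_model: float = Field(1.0, gt=0)

    def to_params(self) -> CSMParams:
        d = self.model_dump()
        d["cn"] = self.cn.to_params()
        return CSMParams(**d)


class RunConfig(_Strict):
    """Top-level pipeline configuration."""

    stages: list[str] = Field(default_factory=lambda: list(STAGES))
    seed: int = Field(0, ge=0)
    output_dir: str = "crzpulse_out"
    trajectories_csv: str | None = None   # input for detect when generate is off
    control_csv: str | None = None        # negative-control records for thresholds
    generator: GeneratorConfig = Field(default_factory=GeneratorConfig)
    thresholds: ThresholdConfig = Field(default_factory=ThresholdConfig)
    tdm: TdmConfig = Field(default_factory=TdmConfig)
    csm: CsmConfig = Field(default_factory=CsmConfig)
    min_interval_sec: float = Field(600.0, gt=0)

    @field_validator("stages")
    @classmethod
    def _known_stages(cls, v: list[str]) -> list[str]:
        unknown = set(v) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}; valid: {STAGES}")
        return v


def validate_config(path: str | Path | None = None, data: dict | None = None) -> RunConfig:
    """Load and schema-validate a YAML config; defaults fill missing keys.

    An empty file yields the all-defaults configuration.  Type and range
    violations raise with the offending key path in the message.
    """
    if data is None:
        text = Path(path).read_text() if path is not None else ""
        data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    return RunConfig.model_validate(data)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2**31) from the master seed."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([master_seed, STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))
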