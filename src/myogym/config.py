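"""Structured run configuration with schema validation.

One document gathers every tunable of the pipeline (sampling, windowing,
network hyperparameters, generator dials, game constants) so a run can log
its full resolved configuration. Files are TOML; validation is pydantic.
All seeds are explicit integers, never derived from the wall clock.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

from pydantic import BaseModel, Field


class FeatureSection(BaseModel):
    fs: float = Field(1000.0, gt=0)
    window_ms: float = Field(128.0, gt=0)
    step_ms: float = Field(50.0, gt=0)
    zc_threshold: float = Field(0.0, ge=0)
    ssc_threshold: float = Field(0.0, ge=0)


class RegressorSection(BaseModel):
    seed: int = 0
    batch_size: int = Field(64, ge=1)
    validation_fraction: float = Field(0.10, gt=0, lt=1)
    patience: int = Field(10, ge=1)
    max_epochs: int = Field(500, ge=1)
    learning_rate: float = Field(1e-3, gt=0)


class GeneratorSection(BaseModel):
    seed: int = 0
    overlap: float = Field(0.2, ge=0, le=1)
    noise: float = Field(0.05, ge=0)
    amplitude_jitter: float = Field(0.1, ge=0)
    ramp_s: float = Field(1.0, gt=0)
    plateau_s: float = Field(5.0, gt=0)


class ControlSection(BaseModel):
    scale: float = Field(100.0, gt=0)
    filter_taps: int = Field(4, ge=1)


class RunConfig(BaseModel):
    """Top-level resolved configuration for a reproducible run."""

    schema_version: int = 1
    features: FeatureSection = FeatureSection()
    regressor: RegressorSection = RegressorSection()
    generator: GeneratorSection = GeneratorSection()
    control: ControlSection = ControlSection()


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a TOML run configuration."""
    path = Path(path)
    try:
        data = tomllib.loads(path.read_text())
    except tomllib.TOMLDecodeError as exc:
        raise ValueError(f"malformed config file {path}: {exc}") from exc
    version = data.get("schema_version", 1)
    if version != 1:
        raise ValueError(
            f"config {path} has schema_version {version}; this build "
            "understands version 1"
        )
    return RunConfig.model_validate(data)
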