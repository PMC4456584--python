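"""Experiment configuration schema (YAML) with strict validation.

An experiment file names a preset plus seed/scale/overrides; unknown keys
are rejected with field-level messages so unit mistakes (all physical
quantities carry their units in the field names of the parameter
dataclasses) surface before anything runs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .presets import PRESETS

__all__ = ["ExperimentConfig", "load_config", "validate_config"]


class ExperimentConfig(BaseModel):
    """One reproducible experiment: preset + seed + scale + overrides."""

    model_config = ConfigDict(extra="forbid")

    preset: str
    model: Literal["rate", "spiking", "balance"] | None = None
    seed: int = 0
    scale: float = Field(default=0.25, gt=0.0, le=1.0)
    out_dir: str | None = None
    overrides: dict[str, float | int | str | list] = Field(default_factory=dict)

    @field_validator("preset")
    @classmethod
    def _known_preset(cls, v: str) -> str:
        if v not in PRESETS:
            raise ValueError(f"unknown preset {v!r}; available: {sorted(PRESETS)}")
        return v

    def resolved(self) -> dict:
        """Full parameter dump for provenance / round-trip re-runs."""
        return self.model_dump()


def load_config(path) -> ExperimentConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return ExperimentConfig(**raw)


def validate_config(path) -> ExperimentConfig:
    """Load and validate; pydantic reports offending fields on failure."""
    return load_config(path)
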