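"""Validated pipeline configuration (JSON-serializable, pydantic-checked).

One config drives the whole run: simulate → segment → render → train →
evaluate → cluster → timeline → embed.  Defaults follow the study protocol
the analysis is built around: 30-s segments, 5 folds, 10-min bins, 1000
permutations at alpha 0.05, and a similarity threshold of d = 0.5.  Unknown
keys are rejected and all errors are reported together.
"""

from __future__ import annotations

import json
import zlib

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .presets import ETHANOL_PRESETS

__all__ = ["PipelineConfig", "validate_config", "stage_seed"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ArenaConfig(_Strict):
    center_x: float = 120.0
    center_y: float = 120.0
    radius: float = Field(100.0, gt=0)


class DesignConfig(_Strict):
    """Which preset concentrations to simulate, and at what scale."""

    concentrations: list[float] = [0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0]
    n_fish_per_condition: int = Field(12, gt=0)
    duration_seconds: float = Field(5400.0, gt=0)
    fps: float = Field(25.0, gt=0)
    arena: ArenaConfig = ArenaConfig()

    @model_validator(mode="after")
    def _known_presets(self):
        unknown = [c for c in self.concentrations if c not in ETHANOL_PRESETS]
        if unknown:
            raise ValueError(f"no preset regime for concentrations {unknown}")
        return self


class RenderSection(_Strict):
    image_size: int = Field(64, ge=32)
    line_width: int = Field(1, ge=1)
    colormap: str = "viridis"
    speed_norm: str = "segment_minmax"
    margin: float = Field(0.05, ge=0, lt=0.5)


class TrainSection(_Strict):
    backbone: str = "small_cnn"
    learning_rate: float = Field(1e-3, gt=0)
    beta1: float = Field(0.9, ge=0, lt=1)
    gamma: float = Field(2.0, ge=0)
    epochs: int = Field(6, ge=0)
    batch_size: int = Field(32, gt=0)


class PipelineConfig(_Strict):
    seed: int = 0
    design: DesignConfig = DesignConfig()
    window_seconds: float = Field(30.0, gt=0)
    render: RenderSection = RenderSection()
    train: TrainSection = TrainSection()
    k_folds: int = Field(5, gt=1)
    bin_minutes: float = Field(10.0, gt=0)
    n_permutations: int = Field(1000, ge=100)
    alpha: float = Field(0.05, gt=0, lt=1)
    similarity_threshold: float = Field(0.5, gt=0)
    save_images: bool = False
    output_dir: str = "swimclass_run"

    @model_validator(mode="after")
    def _cross_field(self):
        if self.k_folds > self.design.n_fish_per_condition:
            raise ValueError(
                f"k_folds={self.k_folds} exceeds n_fish_per_condition="
                f"{self.design.n_fish_per_condition}")
        return self

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return f"{zlib.crc32(payload.encode()):08x}"


def validate_config(path) -> PipelineConfig:
    """Load and validate a JSON config; pydantic reports all errors at once."""
    with open(path) as fh:
        data = json.load(fh)
    return PipelineConfig.model_validate(data)


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, from the master seed."""
    return (int(master) * 2654435761 + zlib.crc32(stage.encode())) % (2**31)
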