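"""Run configuration: validated, YAML-serializable hyperparameters.

Defaults mirror the published training protocol: AdamW with learning rate
1e-3 and weight decay 0.1, a warmup-cosine schedule, 100 pretraining epochs
at batch size 1, encoder depths [2, 2, 6, 2] and decoder depths [2, 2, 2],
patch size 4, normalization window [112, 1000].
"""

from __future__ import annotations

from pathlib import Path
from typing import Tuple

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator


class ModelConfig(BaseModel):
    patch_size: int = 4
    base_channels: int = 32
    encoder_depths: Tuple[int, ...] = (2, 2, 6, 2)
    decoder_depths: Tuple[int, ...] = (2, 2, 2)
    state_size: int = 16
    dw_kernel: int = 3
    expansion: int = 2
    out_classes: int = 2
    input_channels: int = 1

    @model_validator(mode="after")
    def _stages(self):
        if len(self.encoder_depths) != len(self.decoder_depths) + 1:
            raise ValueError("encoder must have one more stage than decoder")
        return self

    @property
    def n_stages(self) -> int:
        return len(self.encoder_depths)

    @property
    def divisor(self) -> int:
        """Spatial dims must be divisible by patch_size * 2**(stages-1)."""
        return self.patch_size * 2 ** (self.n_stages - 1)


class SSLConfig(BaseModel):
    lambdas: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    temperature: float = Field(0.1, gt=0)
    rotation_classes: int = 4
    exchange_patch: int = 30
    n_exchanges: int = 6
    proj_dim: int = 128
    epochs: int = 100
    batch_pairs: int = Field(4, ge=2)
    # Warmup-cosine horizon in epochs; None means the executed run length.
    schedule_epochs: int | None = Field(None, ge=1)

    @field_validator("lambdas")
    @classmethod
    def _nonneg(cls, v):
        if any(x < 0 for x in v):
            raise ValueError("loss weights must be non-negative")
        return v


class TrainConfig(BaseModel):
    lr: float = 1e-3
    weight_decay: float = 0.1
    epochs: int = 100
    warmup_fraction: float = Field(0.1, ge=0.0, le=1.0)
    batch_size: int = 1
    # Warmup-cosine horizon in epochs.  None: the schedule spans the run
    # that is actually executed.  Set to the full recipe length (e.g. 100)
    # to run a shorter budget as a truncation of that recipe, preserving
    # its learning-rate trajectory instead of compressing it.
    schedule_epochs: int | None = Field(None, ge=1)


class PreprocessConfig(BaseModel):
    lo: float = 112.0
    hi: float = 1000.0
    clip: bool = True
    tile_shape: Tuple[int, int, int] = (64, 256, 256)
    tile_overlap: Tuple[int, int, int] = (8, 32, 32)

    @model_validator(mode="after")
    def _window(self):
        if self.hi <= self.lo:
            raise ValueError("hi must exceed lo")
        return self


class RunConfig(BaseModel):
    model: ModelConfig = ModelConfig()
    ssl: SSLConfig = SSLConfig()
    train: TrainConfig = TrainConfig()
    preprocess: PreprocessConfig = PreprocessConfig()
    seed: int = 0


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(payload)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(mode="json"), fh, sort_keys=False)
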