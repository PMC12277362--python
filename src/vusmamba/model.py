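"""U-shaped selective-state-space segmentation network.

Encoder: patch embedding (x4 downsampling) followed by stages of VSS blocks
with patch merging between them (default depths [2, 2, 6, 2], channels
C, 2C, 4C, 8C).  Decoder: patch expanding, skip-connection fusion
(concatenate + linear projection) and VSS blocks (depths [2, 2, 2]),
a final x4 patch expand back to input resolution and a 1x1x1 convolution
(linear over channels) to per-voxel class scores.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict

import numpy as np
import yaml

from . import autodiff as ad
from .autodiff import Tensor
from .config import ModelConfig
from .layers import (Linear, Module, PatchEmbed, PatchExpand, PatchMerge,
                     VSSBlock)


class VUSMamba(Module):
    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        self.config = config or ModelConfig()
        cfg = self.config
        rng = np.random.default_rng(seed)
        C = cfg.base_channels
        n = cfg.n_stages

        self.patch_embed = PatchEmbed(rng, cfg.patch_size, cfg.input_channels, C)
        self.encoder = []
        self.merges = []
        for i, depth in enumerate(cfg.encoder_depths):
            width = C * 2 ** i
            self.encoder.append([
                VSSBlock(rng, width, cfg.state_size, cfg.expansion, cfg.dw_kernel)
                for _ in range(depth)])
            if i < n - 1:
                self.merges.append(PatchMerge(rng, width))

        self.expands = []
        self.skip_fusions = []
        self.decoder = []
        for j, depth in enumerate(cfg.decoder_depths):
            # decoder stage j runs at encoder-stage (n-2-j) width
            width = C * 2 ** (n - 2 - j)
            self.expands.append(PatchExpand(rng, width * 2, 2, width))
            self.skip_fusions.append(Linear(rng, 2 * width, width))
            self.decoder.append([
                VSSBlock(rng, width, cfg.state_size, cfg.expansion, cfg.dw_kernel)
                for _ in range(depth)])

        head_width = max(C // cfg.patch_size, cfg.out_classes)
        self.final_expand = PatchExpand(rng, C, 4, head_width)
        self.head = Linear(rng, head_width, cfg.out_classes)

    # -- forward ---------------------------------------------------------
    def _check_shape(self, shape) -> None:
        div = self.config.divisor
        bad = [s for s in shape if s % div]
        if bad:
            pads = {s: (div - s % div) % div for s in shape}
            raise ValueError(
                f"input shape {tuple(shape)} must be divisible by {div}; "
                f"pad by {tuple(pads[s] for s in shape)} voxels")

    def encode(self, volume) -> tuple[Tensor, list[Tensor]]:
        """Run the encoder; returns (bottleneck grid, per-stage skips)."""
        x = volume if isinstance(volume, Tensor) else Tensor(np.asarray(volume, float))
        self._check_shape(x.shape[:3])
        z = self.patch_embed(x)
        skips = []
        for i, stage in enumerate(self.encoder):
            for block in stage:
                z = block(z)
            if i < len(self.merges):
                skips.append(z)
                z = self.merges[i](z)
        return z, skips

    def decode_features(self, z: Tensor, skips: list[Tensor]) -> Tensor:
        """Decoder up to (but excluding) the classification head."""
        for j, stage in enumerate(self.decoder):
            z = self.expands[j](z)
            skip = skips[-(j + 1)]
            z = self.skip_fusions[j](ad.concat([z, skip], axis=-1))
            for block in stage:
                z = block(z)
        return self.final_expand(z)

    def decode(self, z: Tensor, skips: list[Tensor]) -> Tensor:
        return self.head(self.decode_features(z, skips))

    def forward(self, volume) -> Tensor:
        """Volume (D,H,W) -> class scores (D,H,W,out_classes)."""
        z, skips = self.encode(volume)
        return self.decode(z, skips)

    __call__ = forward

    def calibrate_head(self, foreground_prior: float) -> None:
        """Prior-matched classifier initialization for imbalanced volumes.

        Zeroes the head weights and sets the foreground bias to the logit of
        the class prior, so the untrained network already predicts the
        background/foreground base rates instead of spending early updates
        unlearning an arbitrary prior.
        """
        p = float(foreground_prior)
        if not 0.0 < p < 1.0:
            raise ValueError(f"foreground prior must be in (0, 1), got {p}")
        self.head.weight.data[:] = 0.0
        self.head.bias.data[:] = 0.0
        self.head.bias.data[1] = np.log(p / (1.0 - p))

    def predict_proba(self, volume) -> np.ndarray:
        """Foreground probability map, no gradient tape."""
        with ad.no_grad():
            scores = self.forward(volume)
            probs = ad.softmax(scores, axis=-1)
        return probs.data[..., 1]


# -- checkpoints -----------------------------------------------------------

def save_checkpoint(model: Module, path: str | Path,
                    extra: Dict | None = None) -> None:
    """Weights as .npz plus a YAML sidecar of the architecture config."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    sidecar = path.with_suffix(".yaml")
    payload = {"model": model.config.model_dump(mode="json")}
    if extra:
        payload.update(extra)
    with open(sidecar, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_checkpoint(path: str | Path) -> VUSMamba:
    path = Path(path)
    sidecar = path.with_suffix(".yaml")
    with open(sidecar) as fh:
        payload = yaml.safe_load(fh)
    cfg = ModelConfig.model_validate(payload["model"])
    model = VUSMamba(cfg)
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as npz:
        model.load_state_dict(dict(npz))
    return model
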