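"""Supervised fine-tuning, tiled inference and voxel-wise evaluation.

Fine-tuning optimizes Dice + cross-entropy on binary foreground masks with
AdamW under a warmup-cosine schedule.  Inference tiles the volume, applies
softmax foreground probability per tile and mean-blends overlaps.  Metrics:

    DSC = 2TP / (2TP + FP + FN),   Jc = TP / (TP + FP + FN),
    Sst = TP / (TP + FN).
"""

from __future__ import annotations

import copy
import dataclasses
import warnings
from typing import Dict, List, Sequence, Tuple

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .config import RunConfig
from .io import IntensityVolume, LabelMask
from .model import VUSMamba
from .optim import AdamW, warmup_cosine_lr
from .preprocessing import stitch_tiles, tile_volume


@dataclasses.dataclass
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def confusion(pred: LabelMask | np.ndarray, gt: LabelMask | np.ndarray) -> ConfusionCounts:
    p = (pred.data if isinstance(pred, LabelMask) else np.asarray(pred)).astype(bool)
    g = (gt.data if isinstance(gt, LabelMask) else np.asarray(gt)).astype(bool)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {g.shape}")
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = int(np.count_nonzero(~p & ~g))
    return ConfusionCounts(tp, fp, fn, tn)


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (empty denominator); returning NaN")
        return float("nan")
    return num / den


def dsc(c: ConfusionCounts) -> float:
    return _safe_ratio(2 * c.TP, 2 * c.TP + c.FP + c.FN, "DSC")


def jc(c: ConfusionCounts) -> float:
    return _safe_ratio(c.TP, c.TP + c.FP + c.FN, "Jc")


def sst(c: ConfusionCounts) -> float:
    return _safe_ratio(c.TP, c.TP + c.FN, "Sst")


def evaluate_masks(pred, gt) -> Dict[str, float]:
    c = confusion(pred, gt)
    return {"DSC": dsc(c), "Jc": jc(c), "Sst": sst(c)}


def binarize(prob: np.ndarray, threshold: float = 0.5,
             voxel_size_um=(2.0, 2.0, 2.0)) -> LabelMask:
    return LabelMask(np.asarray(prob) >= threshold, voxel_size_um)


# -- training ----------------------------------------------------------------

def dice_ce_loss(scores: Tensor, gt: np.ndarray, eps: float = 1e-6) -> Tensor:
    """Soft-Dice (foreground) plus voxel cross-entropy on 2-class scores."""
    g = np.asarray(gt, float)
    logp = ad.log_softmax(scores, axis=-1)
    onehot = np.stack([1.0 - g, g], axis=-1)
    ce = -ad.mean(ad.sum_(logp * onehot, axis=-1))
    p_fg = ad.exp(logp[..., 1])
    inter = ad.sum_(p_fg * g)
    denom = ad.sum_(p_fg) + float(g.sum())
    dice = (inter * 2.0 + eps) * ad.power(denom + eps, -1.0)
    return ce + (1.0 - dice)


def _as_pair_arrays(pairs) -> List[Tuple[np.ndarray, np.ndarray]]:
    out = []
    for img, msk in pairs:
        a = img.data if isinstance(img, IntensityVolume) else np.asarray(img, float)
        b = msk.data if isinstance(msk, LabelMask) else np.asarray(msk)
        out.append((a, b.astype(bool)))
    return out


def validation_dsc(model: VUSMamba, pairs, threshold: float = 0.5) -> float:
    """Micro-averaged DSC over held-out tiles."""
    tp = fp = fn = 0
    for img, msk in _as_pair_arrays(pairs):
        pred = model.predict_proba(img) >= threshold
        c = confusion(pred, msk)
        tp, fp, fn = tp + c.TP, fp + c.FP, fn + c.FN
    return _safe_ratio(2 * tp, 2 * tp + fp + fn, "DSC")


def finetune(model: VUSMamba, pairs, cfg: RunConfig,
             val_pairs=None, epochs: int | None = None
             ) -> Tuple[VUSMamba, List[Dict[str, float]]]:
    """Dice + cross-entropy fine-tuning; returns model at the best-DSC epoch.

    When no validation pairs are given the best checkpoint is tracked on the
    training tiles.  Deterministic under cfg.seed.
    """
    data = _as_pair_arrays(pairs)
    if not data:
        raise ValueError("fine-tuning dataset is empty")
    if all(not m.any() for _, m in data):
        warnings.warn("all-background masks: Dice is degenerate")
    epochs = epochs if epochs is not None else cfg.train.epochs
    fg_prior = sum(int(m.sum()) for _, m in data) / sum(m.size for _, m in data)
    if 0.0 < fg_prior < 1.0:
        model.calibrate_head(fg_prior)
    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(model.parameters(), lr=cfg.train.lr,
                weight_decay=cfg.train.weight_decay)
    horizon = max(cfg.train.schedule_epochs or epochs, epochs)
    total_steps = horizon * len(data)
    monitor = val_pairs if val_pairs is not None else pairs
    history: List[Dict[str, float]] = []
    best = (-np.inf, None)
    step = 0
    for _ in range(epochs):
        order = rng.permutation(len(data))
        epoch_loss = 0.0
        for i in order:
            img, msk = data[i]
            opt.zero_grad()
            scores = model.forward(img)
            loss = dice_ce_loss(scores, msk)
            loss.backward()
            lr = warmup_cosine_lr(step, total_steps, cfg.train.lr,
                                  cfg.train.warmup_fraction)
            opt.step(lr)
            step += 1
            epoch_loss += float(loss.data)
        vdsc = validation_dsc(model, monitor)
        history.append({"loss": epoch_loss / len(data), "val_dsc": vdsc})
        if vdsc > best[0]:
            best = (vdsc, copy.deepcopy(model.state_dict()))
    if best[1] is not None:
        model.load_state_dict(best[1])
    return model, history


# -- inference ---------------------------------------------------------------

def _effective_tile(vol_shape, tile_shape, divisor: int) -> tuple[int, ...]:
    tile = []
    for s, t in zip(vol_shape, tile_shape):
        e = min(s, t)
        e -= e % divisor
        if e <= 0:
            raise ValueError(
                f"volume shape {tuple(vol_shape)} below one tile after padding "
                f"(needs at least {divisor} per axis)")
        tile.append(e)
    return tuple(tile)


def predict(volume: IntensityVolume | np.ndarray, model: VUSMamba,
            cfg: RunConfig | None = None) -> np.ndarray:
    """Tiled softmax foreground probability with mean blending, in [0, 1]."""
    cfg = cfg or RunConfig(model=model.config)
    data = volume.data if isinstance(volume, IntensityVolume) else np.asarray(volume, float)
    tile_shape = _effective_tile(data.shape, cfg.preprocess.tile_shape,
                                 model.config.divisor)
    overlap = tuple(min(o, t - 1) for o, t in
                    zip(cfg.preprocess.tile_overlap, tile_shape))
    pieces = []
    for tile, origin in tile_volume(data, tile_shape, overlap):
        pieces.append((model.predict_proba(tile), origin))
    return stitch_tiles(pieces, data.shape)
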