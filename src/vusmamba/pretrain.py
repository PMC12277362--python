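"""Three-task self-supervised pretraining.

Pretext tasks: (1) rotation prediction — a tile is rotated in-plane by one
of {0, 90, 180, 270} degrees about z and a linear head on pooled bottleneck
features classifies the angle (cross-entropy); (2) contrastive encoding —
two augmented views of the same tile are positives, views of other tiles in
the step are negatives, scored with the normalized temperature-scaled
cross-entropy (NT-Xent) over cosine similarities; (3) recovery — random
30^3 patch pairs are swapped ("context-aware volumetric patch exchange")
and the encoder-decoder restores the original tile under an MSE loss.
The combined objective is  l = l1*l_rot + l2*l_contrast + l3*l_recovery
with default weights (1, 1, 1).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Dict, List, Sequence, Tuple

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .config import RunConfig, SSLConfig
from .layers import Linear, Module
from .model import VUSMamba
from .optim import AdamW, warmup_cosine_lr

_EPS = 1e-12


@dataclasses.dataclass
class RotationSample:
    volume: np.ndarray
    label: int  # r in {0,1,2,3}: rotation by 90*r degrees about z


def rotate_tile(tile: np.ndarray, r: int) -> np.ndarray:
    """Rotate by 90*r degrees about z: voxel (z,y,x) -> (z, x, W-1-y) for r=1."""
    if tile.shape[1] != tile.shape[2]:
        raise ValueError(f"in-plane dims must be square, got {tile.shape}")
    return np.rot90(tile, k=-int(r) % 4, axes=(1, 2)).copy()


def make_rotation_sample(tile: np.ndarray, rng: np.random.Generator) -> RotationSample:
    r = int(rng.integers(0, 4))
    return RotationSample(volume=rotate_tile(tile, r), label=r)


def rotation_loss(pred_probs, label: int):
    """Cross-entropy of the predicted rotation-class simplex."""
    if isinstance(pred_probs, Tensor):
        p = pred_probs[int(label)]
        return -ad.log(p + _EPS)
    p = float(np.asarray(pred_probs)[int(label)])
    return -np.log(max(p, _EPS))


def _normalize_rows(e: Tensor) -> Tensor:
    sq = ad.sum_(e * e, axis=-1, keepdims=True)
    return e * ad.power(sq + _EPS, -0.5)


def contrastive_loss(embeddings, pair_index: Sequence[int], temperature: float = 0.1):
    """NT-Xent over 2N embeddings; ``pair_index[i]`` is i's positive partner.

    Mean over anchors of -log softmax(sim(v_i, v_j)/t) with the denominator
    running over all k != i (cosine similarity).
    """
    pair_index = np.asarray(pair_index, int)
    n = len(pair_index)
    if n < 4:
        warnings.warn("fewer than 2 pairs: contrastive loss is degenerate")
    is_tensor = isinstance(embeddings, Tensor)
    e = embeddings if is_tensor else Tensor(np.asarray(embeddings, float))
    en = _normalize_rows(e)
    sim = ad.matmul(en, ad.transpose(en, (1, 0)))
    logits = sim * (1.0 / temperature)
    offdiag = 1.0 - np.eye(n)
    shift = np.max(logits.data, axis=1, keepdims=True)
    z = ad.exp(logits - shift) * offdiag
    denom = ad.log(ad.sum_(z, axis=1) + _EPS) + Tensor(shift[:, 0])
    pos = logits[np.arange(n), pair_index]
    loss = ad.mean(denom - pos)
    return loss if is_tensor else float(loss.data)


@dataclasses.dataclass
class SwapRecord:
    patch: int
    pairs: List[Tuple[Tuple[int, int, int], Tuple[int, int, int]]]


def patch_exchange(tile: np.ndarray, rng: np.random.Generator,
                   patch: int = 30, n_exchanges: int = 6,
                   max_attempts: int = 2000) -> Tuple[np.ndarray, SwapRecord]:
    """Swap the contents of disjoint patch^3 cube pairs (an involution)."""
    if any(s < patch for s in tile.shape):
        raise ValueError(f"tile {tile.shape} smaller than exchange patch {patch}")
    corners: List[Tuple[int, int, int]] = []

    def overlaps(a, b):
        return all(abs(a[i] - b[i]) < patch for i in range(3))

    attempts = 0
    while len(corners) < 2 * n_exchanges:
        cand = tuple(int(rng.integers(0, s - patch + 1)) for s in tile.shape)
        if all(not overlaps(cand, c) for c in corners):
            corners.append(cand)
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"cannot fit {n_exchanges} disjoint patch pairs of size {patch}")
    out = tile.copy()
    pairs = []
    for a, b in zip(corners[0::2], corners[1::2]):
        sa = tuple(slice(c, c + patch) for c in a)
        sb = tuple(slice(c, c + patch) for c in b)
        out[sa], out[sb] = tile[sb].copy(), tile[sa].copy()
        pairs.append((a, b))
    return out, SwapRecord(patch=patch, pairs=pairs)


def apply_swaps(tile: np.ndarray, record: SwapRecord) -> np.ndarray:
    out = tile.copy()
    p = record.patch
    for a, b in record.pairs:
        sa = tuple(slice(c, c + p) for c in a)
        sb = tuple(slice(c, c + p) for c in b)
        out[sa], out[sb] = tile[sb].copy(), tile[sa].copy()
    return out


def recovery_loss(restored, original):
    """Mean squared error over voxels."""
    if isinstance(restored, Tensor):
        orig = original if isinstance(original, Tensor) else Tensor(np.asarray(original, float))
        if restored.shape != orig.shape:
            raise ValueError(f"shape mismatch {restored.shape} vs {orig.shape}")
        d = restored - orig
        return ad.mean(d * d)
    a = np.asarray(restored, float)
    b = np.asarray(original, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def combined_loss(l_rot, l_con, l_rec, lambdas: Sequence[float] = (1.0, 1.0, 1.0)):
    parts = {"rotation": l_rot, "contrastive": l_con, "recovery": l_rec}
    for name, part in parts.items():
        val = part.data if isinstance(part, Tensor) else part
        if not np.all(np.isfinite(val)):
            raise FloatingPointError(f"non-finite {name} loss component")
    l1, l2, l3 = lambdas
    return l_rot * l1 + l_con * l2 + l_rec * l3


class SSLHeads(Module):
    """Rotation classifier, contrastive projection MLP and recovery head."""

    def __init__(self, model: VUSMamba, ssl: SSLConfig, seed: int = 0):
        rng = np.random.default_rng(seed + 1)
        cfg = model.config
        bottleneck = cfg.base_channels * 2 ** (cfg.n_stages - 1)
        head_width = model.final_expand.out_channels
        self.rot_head = Linear(rng, bottleneck, ssl.rotation_classes)
        self.proj1 = Linear(rng, bottleneck, ssl.proj_dim)
        self.proj2 = Linear(rng, ssl.proj_dim, ssl.proj_dim)
        self.recon_head = Linear(rng, head_width, 1)

    def rotation_probs(self, bottleneck: Tensor) -> Tensor:
        pooled = ad.mean(bottleneck, axis=(0, 1, 2))
        return ad.softmax(self.rot_head(pooled), axis=-1)

    def project(self, bottleneck: Tensor) -> Tensor:
        pooled = ad.mean(bottleneck, axis=(0, 1, 2))
        return self.proj2(ad.silu(self.proj1(pooled)))

    def reconstruct(self, model: VUSMamba, z: Tensor, skips) -> Tensor:
        feats = model.decode_features(z, skips)
        out = self.recon_head(feats)
        return ad.reshape(out, out.shape[:3])


def pretrain(tiles: Sequence[np.ndarray], model: VUSMamba, cfg: RunConfig,
             heads: SSLHeads | None = None, epochs: int | None = None
             ) -> Tuple[SSLHeads, List[Dict[str, float]]]:
    """Optimize the combined self-supervised objective over unlabeled tiles.

    Per step the loop draws ``batch_pairs`` tiles, builds a rotated view and
    a patch-exchanged view of each, runs rotation/recovery losses per tile
    and one NT-Xent term across the step, and takes an AdamW step under a
    warmup-cosine schedule.  Fully deterministic under cfg.seed.
    """
    if len(tiles) == 0:
        raise ValueError("pretraining corpus is empty")
    ssl = cfg.ssl
    epochs = epochs if epochs is not None else ssl.epochs
    rng = np.random.default_rng(cfg.seed)
    if heads is None:
        heads = SSLHeads(model, ssl, cfg.seed)
    params = model.parameters() + heads.parameters()
    opt = AdamW(params, lr=cfg.train.lr, weight_decay=cfg.train.weight_decay)
    chunk = min(ssl.batch_pairs, len(tiles))
    steps_per_epoch = max(len(tiles) // chunk, 1)
    horizon = max(ssl.schedule_epochs or epochs, epochs)
    total_steps = horizon * steps_per_epoch
    history: List[Dict[str, float]] = []
    step = 0
    for _ in range(epochs):
        order = rng.permutation(len(tiles))
        sums = {"rotation": 0.0, "contrastive": 0.0, "recovery": 0.0, "total": 0.0}
        for s in range(steps_per_epoch):
            idx = order[s * chunk:(s + 1) * chunk]
            opt.zero_grad()
            embeddings: List[Tensor] = []
            pair_index: List[int] = []
            l_rot_sum = None
            l_rec_sum = None
            for tile in (tiles[i] for i in idx):
                rot = make_rotation_sample(tile, rng)
                corrupted, _ = patch_exchange(
                    tile, rng, min(ssl.exchange_patch, min(tile.shape)),
                    ssl.n_exchanges)
                z_rot, _ = model.encode(rot.volume)
                probs = heads.rotation_probs(z_rot)
                l_rot = rotation_loss(probs, rot.label)
                z_rec, skips = model.encode(corrupted)
                restored = heads.reconstruct(model, z_rec, skips)
                l_rec = recovery_loss(restored, tile)
                k = len(embeddings)
                embeddings.extend([heads.project(z_rot), heads.project(z_rec)])
                pair_index.extend([k + 1, k])
                l_rot_sum = l_rot if l_rot_sum is None else l_rot_sum + l_rot
                l_rec_sum = l_rec if l_rec_sum is None else l_rec_sum + l_rec
            emb = ad.concat([ad.reshape(e, (1, e.shape[0])) for e in embeddings], axis=0)
            l_con = contrastive_loss(emb, pair_index, ssl.temperature)
            n_tiles = len(idx)
            l_rot_mean = l_rot_sum * (1.0 / n_tiles)
            l_rec_mean = l_rec_sum * (1.0 / n_tiles)
            total = combined_loss(l_rot_mean, l_con, l_rec_mean, ssl.lambdas)
            total.backward()
            lr = warmup_cosine_lr(step, total_steps, cfg.train.lr,
                                  cfg.train.warmup_fraction)
            opt.step(lr)
            step += 1
            sums["rotation"] += float(l_rot_mean.data)
            sums["contrastive"] += float(l_con.data)
            sums["recovery"] += float(l_rec_mean.data)
            sums["total"] += float(total.data)
        history.append({k: v / steps_per_epoch for k, v in sums.items()})
    return heads, history
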