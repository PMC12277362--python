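"""Intensity normalization and tiled extraction/stitching.

Normalization maps raw intensities affinely, N(x) = (x - lo) / (hi - lo),
with lo = 112 and hi = 1000 by default, optionally clipping to [0, 1].
Tiling covers a large volume with fixed-shape windows whose edge tiles are
shifted inward so every tile has the full shape; stitching averages
overlapping predictions.
"""

from __future__ import annotations

import dataclasses
from typing import List, Sequence, Tuple

import numpy as np

from .io import IntensityVolume


@dataclasses.dataclass
class NormalizationParams:
    lo: float = 112.0
    hi: float = 1000.0
    clip: bool = True

    def __post_init__(self):
        if self.hi <= self.lo:
            raise ValueError(f"hi ({self.hi}) must exceed lo ({self.lo})")


def normalize(volume: IntensityVolume | np.ndarray,
              params: NormalizationParams | None = None) -> IntensityVolume | np.ndarray:
    """Affine intensity rescaling, clipped to [0, 1] when params.clip."""
    params = params or NormalizationParams()
    data = volume.data if isinstance(volume, IntensityVolume) else np.asarray(volume, float)
    out = (data - params.lo) / (params.hi - params.lo)
    if params.clip:
        out = np.clip(out, 0.0, 1.0)
    if isinstance(volume, IntensityVolume):
        v = IntensityVolume.__new__(IntensityVolume)
        v.data = out
        v.voxel_size_um = volume.voxel_size_um
        v.channel = volume.channel
        return v
    return out


def _axis_starts(size: int, tile: int, overlap: int) -> List[int]:
    if tile > size:
        raise ValueError(f"tile size {tile} exceeds volume extent {size}")
    if overlap >= tile:
        raise ValueError(f"overlap {overlap} must be smaller than tile {tile}")
    step = tile - overlap
    starts = list(range(0, size - tile + 1, step))
    if starts[-1] + tile < size:
        starts.append(size - tile)  # edge tile shifted inward
    return starts


def tile_volume(volume: IntensityVolume | np.ndarray,
                tile_shape: Sequence[int],
                overlap: Sequence[int] = (0, 0, 0)
                ) -> List[Tuple[np.ndarray, Tuple[int, int, int]]]:
    """Cover the volume with full-shape tiles; returns (tile, origin) pairs."""
    data = volume.data if isinstance(volume, IntensityVolume) else np.asarray(volume)
    tile_shape = tuple(int(t) for t in tile_shape)
    overlap = tuple(int(o) for o in overlap)
    axes_starts = [_axis_starts(s, t, o)
                   for s, t, o in zip(data.shape, tile_shape, overlap)]
    out = []
    for z0 in axes_starts[0]:
        for y0 in axes_starts[1]:
            for x0 in axes_starts[2]:
                tile = data[z0:z0 + tile_shape[0],
                            y0:y0 + tile_shape[1],
                            x0:x0 + tile_shape[2]]
                out.append((tile, (z0, y0, x0)))
    return out


def stitch_tiles(pieces: Sequence[Tuple[np.ndarray, Sequence[int]]],
                 out_shape: Sequence[int]) -> np.ndarray:
    """Mean-blend overlapping tiles back into a full volume."""
    out_shape = tuple(int(s) for s in out_shape)
    acc = np.zeros(out_shape)
    cnt = np.zeros(out_shape)
    for tile, origin in pieces:
        tile = np.asarray(tile)
        sl = tuple(slice(o, o + s) for o, s in zip(origin, tile.shape))
        if any(o < 0 or o + s > full for o, s, full in
               zip(origin, tile.shape, out_shape)):
            raise ValueError(f"tile at {tuple(origin)} exceeds bounds {out_shape}")
        acc[sl] += tile
        cnt[sl] += 1
    if np.any(cnt == 0):
        raise ValueError("stitching left uncovered voxels")
    return acc / cnt
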