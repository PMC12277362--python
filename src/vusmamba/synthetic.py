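"""Synthetic multi-FISH phantoms with known ground truth.

The generator emulates the structure of thick-slice multi-FISH sub-volumes:
a Hoechst channel in which every nucleus appears as a bright ellipsoid, and
marker channels (Vglut1, Vgat) in which only flagged cells carry signal,
modeled as a perinuclear shell that overlaps the outermost nuclear voxels
(FISH puncta aggregate around the nucleus).  Nuclei are axis-aligned
ellipsoids with semi-axes drawn uniformly from ``radius_range_um``.  The
default 3.0-5.0 um matches the 110-540 um^3 validity window used downstream
(equivalent-sphere radii 2.97-5.05 um): semi-axis products span 27-125 um^3,
i.e. volumes (4/3)*pi*abc of 113-524 um^3.  Intensities are blurred masks times a foreground
mean plus background plus additive Gaussian noise.  Everything is
deterministic under the spec seed.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .io import CellRecord, IntensityVolume, LabelMask

SHELL_VOXELS = 2          # perinuclear shell thickness (dilation radius)
_CLEARANCE_VOXELS = 1     # gap between a shell and any other nucleus


@dataclasses.dataclass
class PhantomSpec:
    shape: Tuple[int, int, int] = (64, 256, 256)
    voxel_size_um: Tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_cells: int = 300
    radius_range_um: Tuple[float, float] = (3.0, 5.0)
    p_vglut1: float = 0.45
    p_vgat: float = 0.35
    p_double: float = 0.10
    intensity_fg: float = 800.0
    intensity_bg: float = 150.0
    noise_sd: float = 20.0
    blur_sigma_um: float = 1.0
    seed: int = 0

    def __post_init__(self):
        probs = (self.p_vglut1, self.p_vgat, self.p_double)
        if any(p < 0 or p > 1 for p in probs) or sum(probs) > 1 + 1e-12:
            raise ValueError("expression probabilities must lie in [0,1] and "
                             "sum (with p_neither) to 1")
        if self.radius_range_um[0] > self.radius_range_um[1]:
            raise ValueError("radius_range_um must be (min, max)")


@dataclasses.dataclass
class Phantom:
    channels: Dict[str, IntensityVolume]
    gt_masks: Dict[str, LabelMask]
    gt_cells: List[CellRecord]
    truth_boundary: "BoundaryTruth | None" = None


@dataclasses.dataclass
class BoundaryTruth:
    """Sampled true boundary x = f(y) in in-plane micrometers."""
    dv_um: np.ndarray   # y (H axis) samples, ascending
    x_um: np.ndarray    # in-plane boundary position per sample
    mixing_width_um: float = 0.0


class PackingError(RuntimeError):
    pass


def _ellipsoid_mask(center_vox, semi_vox, shape):
    """Boolean ellipsoid within its bounding box; returns (bbox slices, mask)."""
    lo = [max(int(math.floor(c - r)) - 1, 0) for c, r in zip(center_vox, semi_vox)]
    hi = [min(int(math.ceil(c + r)) + 2, s) for c, r, s in zip(center_vox, semi_vox, shape)]
    grids = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center_vox, semi_vox))
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    return sl, q <= 1.0


def _place_nuclei(rng: np.random.Generator, shape, voxel_size, n_cells,
                  radius_range_um, max_attempts_per_cell: int = 200,
                  sampler: Callable[[np.random.Generator], np.ndarray] | None = None):
    """Rejection-sample non-overlapping ellipsoids.

    A conservative sphere test keeps every nucleus at least
    SHELL_VOXELS + _CLEARANCE_VOXELS voxels away from any other nucleus so
    perinuclear shells never touch a foreign nucleus.
    """
    voxel_size = np.asarray(voxel_size, float)
    shape = tuple(shape)
    margin_um = (SHELL_VOXELS + _CLEARANCE_VOXELS) * float(voxel_size.max())
    centers: list[np.ndarray] = []   # in um
    semis: list[np.ndarray] = []     # in um, per-axis
    reach: list[float] = []          # max semi-axis in um
    extent_um = np.asarray(shape) * voxel_size
    placed = []
    for i in range(n_cells):
        ok = False
        for _ in range(max_attempts_per_cell):
            semi_um = rng.uniform(radius_range_um[0], radius_range_um[1], size=3)
            if sampler is None:
                c_um = rng.uniform(semi_um + 1.0, extent_um - semi_um - 1.0)
            else:
                c_um = sampler(rng)
                if np.any(c_um < semi_um + 1.0) or np.any(c_um > extent_um - semi_um - 1.0):
                    continue
            r = float(semi_um.max())
            if all(np.linalg.norm(c_um - c2) > r + r2 + margin_um
                   for c2, r2 in zip(centers, reach)):
                centers.append(c_um)
                semis.append(semi_um)
                reach.append(r)
                ok = True
                break
        if not ok:
            raise PackingError(
                f"could not place {n_cells} non-overlapping nuclei; achieved {i}")
        placed.append((c_um / voxel_size, semi_um / voxel_size))
    return placed  # list of (center_vox, semi_vox)


def _draw_flags(rng: np.random.Generator, spec: PhantomSpec) -> Dict[str, bool]:
    u = rng.random()
    if u < spec.p_vglut1:
        return {"vglut1": True, "vgat": False}
    if u < spec.p_vglut1 + spec.p_vgat:
        return {"vglut1": False, "vgat": True}
    if u < spec.p_vglut1 + spec.p_vgat + spec.p_double:
        return {"vglut1": True, "vgat": True}
    return {"vglut1": False, "vgat": False}


def _render_channel(mask: np.ndarray, spec: PhantomSpec,
                    rng: np.random.Generator) -> np.ndarray:
    sigma = [spec.blur_sigma_um / v for v in spec.voxel_size_um]
    img = ndimage.gaussian_filter(mask.astype(float), sigma=sigma)
    img = img * spec.intensity_fg + spec.intensity_bg
    img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(img, 0.0, None)


def _build_phantom(spec: PhantomSpec, placed, flags_per_cell,
                   rng: np.random.Generator,
                   truth: BoundaryTruth | None = None) -> Phantom:
    shape = tuple(spec.shape)
    vs = spec.voxel_size_um
    voxvol = float(np.prod(vs))
    nuc = np.zeros(shape, bool)
    marker = {"vglut1": np.zeros(shape, bool), "vgat": np.zeros(shape, bool)}
    cells: List[CellRecord] = []
    for i, ((c_vox, s_vox), flags) in enumerate(zip(placed, flags_per_cell)):
        sl, m = _ellipsoid_mask(c_vox, s_vox, shape)
        nuc[sl] |= m
        idx = np.argwhere(m)
        centroid_local = idx.mean(axis=0)
        centroid_vox = tuple(centroid_local[a] + sl[a].start for a in range(3))
        centroid_um = tuple(v * s for v, s in zip(centroid_vox, vs))
        cells.append(CellRecord(
            cell_id=i + 1, centroid_vox=centroid_vox, centroid_um=centroid_um,
            volume_um3=float(m.sum()) * voxvol, genes=dict(flags)))
        if flags["vglut1"] or flags["vgat"]:
            # perinuclear shell: dilated nucleus minus eroded core, padded
            # locally so dilation is not clipped by the bbox
            pad = SHELL_VOXELS
            lo = [max(s.start - pad, 0) for s in sl]
            hi = [min(s.stop + pad, dim) for s, dim in zip(sl, shape)]
            big = np.zeros(tuple(h - l for l, h in zip(lo, hi)), bool)
            inner = tuple(slice(s.start - l, s.stop - l) for s, l in zip(sl, lo))
            big[inner] = m
            shell = ndimage.binary_dilation(big, iterations=SHELL_VOXELS)
            shell &= ~ndimage.binary_erosion(big, iterations=1)
            dst = tuple(slice(l, h) for l, h in zip(lo, hi))
            for gene, on in flags.items():
                if on:
                    marker[gene][dst] |= shell
    channels = {
        "hoechst": IntensityVolume(_render_channel(nuc, spec, rng), vs, "hoechst"),
        "vglut1": IntensityVolume(_render_channel(marker["vglut1"], spec, rng), vs, "vglut1"),
        "vgat": IntensityVolume(_render_channel(marker["vgat"], spec, rng), vs, "vgat"),
    }
    gt_masks = {
        "hoechst": LabelMask(nuc, vs),
        "vglut1": LabelMask(marker["vglut1"], vs),
        "vgat": LabelMask(marker["vgat"], vs),
    }
    return Phantom(channels, gt_masks, cells, truth)


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Labeled three-channel phantom with non-overlapping ellipsoidal nuclei."""
    rng = np.random.default_rng(spec.seed)
    placed = _place_nuclei(rng, spec.shape, spec.voxel_size_um,
                           spec.n_cells, spec.radius_range_um)
    flags = [_draw_flags(rng, spec) for _ in placed]
    return _build_phantom(spec, placed, flags, rng)


def generate_boundary_phantom(shape=(16, 256, 256),
                              boundary: Callable[[np.ndarray], np.ndarray] | None = None,
                              n_per_side: int = 250,
                              mixing_width_um: float = 0.0,
                              voxel_size_um=(2.0, 2.0, 2.0),
                              radius_range_um=(3.0, 5.0),
                              seed: int = 0) -> Phantom:
    """Two intermingled populations separated by a planar boundary x = f(y).

    ``boundary`` maps the in-plane DV coordinate y (um, along H) to the ML
    position x (um, along W); default is a vertical line through the middle.
    Cells left of the boundary are Vglut1-flagged, right of it Vgat-flagged;
    inside the mixing band of the given width the side is re-drawn at random.
    The true curve is stored on the phantom for recovery tests.
    """
    vs = np.asarray(voxel_size_um, float)
    extent = np.asarray(shape) * vs
    if boundary is None:
        mid = extent[2] / 2.0
        boundary = lambda y: np.full_like(np.asarray(y, float), mid)
    ys = np.linspace(0.0, extent[1], 257)
    xs = np.asarray(boundary(ys), float)
    if np.any(xs < 0) or np.any(xs > extent[2]):
        raise ValueError("boundary leaves the volume footprint")
    rng = np.random.default_rng(seed)
    spec = PhantomSpec(shape=tuple(shape), voxel_size_um=tuple(vs),
                       n_cells=2 * n_per_side, radius_range_um=radius_range_um,
                       seed=seed)
    placed = _place_nuclei(rng, shape, vs, 2 * n_per_side, radius_range_um)
    flags = []
    for c_vox, _ in placed:
        y_um = c_vox[1] * vs[1]
        x_um = c_vox[2] * vs[2]
        b = float(boundary(np.asarray([y_um]))[0])
        if abs(x_um - b) <= mixing_width_um / 2.0:
            left = rng.random() < 0.5
        else:
            left = x_um < b
        flags.append({"vglut1": bool(left), "vgat": bool(not left)})
    truth = BoundaryTruth(dv_um=ys, x_um=xs, mixing_width_um=mixing_width_um)
    return _build_phantom(spec, placed, flags, rng, truth)


def make_annotation_pairs(phantom: Phantom,
                          tile_shape: Sequence[int] = (64, 256, 256),
                          channel: str = "hoechst"
                          ) -> List[Tuple[IntensityVolume, LabelMask]]:
    """Aligned non-overlapping image/mask tiles for fine-tuning."""
    vol = phantom.channels[channel]
    mask = phantom.gt_masks[channel]
    tile_shape = tuple(int(t) for t in tile_shape)
    if any(t > s for t, s in zip(tile_shape, vol.shape)):
        raise ValueError(f"tile {tile_shape} larger than phantom {vol.shape}")
    pairs = []
    for z0 in range(0, vol.shape[0] - tile_shape[0] + 1, tile_shape[0]):
        for y0 in range(0, vol.shape[1] - tile_shape[1] + 1, tile_shape[1]):
            for x0 in range(0, vol.shape[2] - tile_shape[2] + 1, tile_shape[2]):
                sl = (slice(z0, z0 + tile_shape[0]),
                      slice(y0, y0 + tile_shape[1]),
                      slice(x0, x0 + tile_shape[2]))
                pairs.append((
                    IntensityVolume(vol.data[sl], vol.voxel_size_um, vol.channel),
                    LabelMask(mask.data[sl], mask.voxel_size_um)))
    return pairs
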