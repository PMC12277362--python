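"""Connected-component nucleus detection and cell-type calling.

Nuclei are connected components of the Hoechst foreground mask
(26-connectivity by default).  Components with voxelized volumes between
110 and 540 um^3 (inclusive) are considered valid nuclei.  A cell is called
positive for a marker gene when its nucleus voxels intersect the marker's
foreground mask in at least one voxel (the non-empty-intersection rule);
per-region summaries report densities (per mm^3) and proportions of the
Vglut1-only / Vgat-only / double-positive populations.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .io import CellRecord, LabelMask

VOLUME_BOUNDS_UM3 = (110.0, 540.0)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), bool)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6, 18 or 26")


def label_components(mask: LabelMask | np.ndarray,
                     connectivity: int = 26) -> Tuple[np.ndarray, np.ndarray]:
    """Label foreground components; returns (labels, per-label voxel counts).

    ``counts[k]`` is the size of component k+1.
    """
    data = (mask.data if isinstance(mask, LabelMask) else np.asarray(mask)).astype(bool)
    labels, n = ndimage.label(data, structure=_structure(connectivity))
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    return labels, counts


def extract_cells(labels: np.ndarray,
                  voxel_size_um: Sequence[float] = (2.0, 2.0, 2.0)
                  ) -> List[CellRecord]:
    """One unfiltered record per component: mean-voxel centroid and volume."""
    vs = tuple(float(v) for v in voxel_size_um)
    voxvol = float(np.prod(vs))
    n = int(labels.max())
    if n == 0:
        return []
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    centroids = ndimage.center_of_mass(np.ones_like(labels, dtype=np.uint8),
                                       labels, index=range(1, n + 1))
    records = []
    for k, com in enumerate(centroids, start=1):
        um = tuple(c * s for c, s in zip(com, vs))
        records.append(CellRecord(
            cell_id=k, centroid_vox=tuple(com), centroid_um=um,
            volume_um3=float(counts[k]) * voxvol))
    return records


def filter_valid(cells: List[CellRecord],
                 bounds_um3: Tuple[float, float] = VOLUME_BOUNDS_UM3
                 ) -> List[CellRecord]:
    """Keep records with lo <= volume <= hi (inclusive); order preserved."""
    lo, hi = bounds_um3
    return [c for c in cells if lo <= c.volume_um3 <= hi]


def assign_genes(cells: List[CellRecord], hoechst_labels: np.ndarray,
                 marker_masks: Dict[str, LabelMask | np.ndarray]) -> List[CellRecord]:
    """Flag each cell positive for a gene iff nucleus ∩ marker mask != ∅."""
    out = []
    overlapping: Dict[str, set] = {}
    for gene, mask in marker_masks.items():
        m = (mask.data if isinstance(mask, LabelMask) else np.asarray(mask)).astype(bool)
        if m.shape != hoechst_labels.shape:
            raise ValueError(f"{gene} mask shape {m.shape} does not match "
                             f"labels {hoechst_labels.shape}")
        overlapping[gene] = set(np.unique(hoechst_labels[m])) - {0}
    for c in cells:
        genes = dict(c.genes)
        for gene, labelset in overlapping.items():
            genes[gene] = c.cell_id in labelset
        out.append(dataclasses.replace(c, genes=genes))
    return out


@dataclasses.dataclass
class RegionSummary:
    region_id: str
    n_cells: int
    counts: Dict[str, int]        # vglut1_only / vgat_only / double
    density_per_mm3: Dict[str, float]
    proportions: Dict[str, float]
    region_volume_mm3: float


def _classify(c: CellRecord) -> str | None:
    v, g = c.genes.get("vglut1", False), c.genes.get("vgat", False)
    if v and g:
        return "double"
    if v:
        return "vglut1_only"
    if g:
        return "vgat_only"
    return None


def summarize_region(cells: List[CellRecord], region_mask: LabelMask | np.ndarray,
                     voxel_size_um: Sequence[float] = (2.0, 2.0, 2.0),
                     region_id: str = "region") -> RegionSummary:
    """Densities and proportions of the three populations inside a region.

    Cells are assigned to the region by their centroid voxel.  Proportions
    are relative to all cells in the region, so they sum to 1 exactly when
    every cell expresses at least one gene.
    """
    m = (region_mask.data if isinstance(region_mask, LabelMask)
         else np.asarray(region_mask)).astype(bool)
    nvox = int(m.sum())
    if nvox == 0:
        raise ValueError("empty region mask")
    volume_mm3 = nvox * float(np.prod(voxel_size_um)) * 1e-9
    inside = []
    for c in cells:
        idx = tuple(int(round(v)) for v in c.centroid_vox)
        if all(0 <= i < s for i, s in zip(idx, m.shape)) and m[idx]:
            inside.append(c)
    counts = {"vglut1_only": 0, "vgat_only": 0, "double": 0}
    for c in inside:
        cls = _classify(c)
        if cls is not None:
            counts[cls] += 1
    n = len(inside)
    density = {k: v / volume_mm3 for k, v in counts.items()}
    props = {k: (v / n if n else 0.0) for k, v in counts.items()}
    return RegionSummary(region_id=region_id, n_cells=n, counts=counts,
                         density_per_mm3=density, proportions=props,
                         region_volume_mm3=volume_mm3)


def detect_cells(hoechst_mask: LabelMask | np.ndarray,
                 marker_masks: Dict[str, LabelMask | np.ndarray] | None = None,
                 voxel_size_um: Sequence[float] = (2.0, 2.0, 2.0),
                 connectivity: int = 26,
                 bounds_um3: Tuple[float, float] = VOLUME_BOUNDS_UM3
                 ) -> List[CellRecord]:
    """Full pipeline: label -> extract -> volume filter -> gene assignment."""
    labels, _ = label_components(hoechst_mask, connectivity)
    cells = filter_valid(extract_cells(labels, voxel_size_um), bounds_um3)
    if marker_masks:
        cells = assign_genes(cells, labels, marker_masks)
    return cells
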