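"""Volume, mask and cell-table readers/writers.

Volumes are 3-D grids in (z, y, x) = (D, H, W) order with an explicit
physical voxel size in micrometers; physical coordinates are voxel index
times voxel size (center-of-voxel convention, 0-based).  Supported on-disk
formats: multi-page TIFF, HDF5 and Zarr for volumes, CSV for cell tables.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

Triple = tuple[float, float, float]

CHANNELS = ("hoechst", "vglut1", "vgat", "other")

CELL_TABLE_COLUMNS = ["cell_id", "z_um", "y_um", "x_um", "volume_um3",
                      "vglut1", "vgat"]


def _check_voxel_size(voxel_size_um) -> Triple:
    vs = tuple(float(v) for v in voxel_size_um)
    if len(vs) != 3 or any(v <= 0 for v in vs):
        raise ValueError(f"voxel size must be three positive reals, got {voxel_size_um}")
    return vs


@dataclasses.dataclass
class IntensityVolume:
    """3-D marker fluorescence grid (non-negative, arbitrary units)."""

    data: np.ndarray
    voxel_size_um: Triple = (2.0, 2.0, 2.0)
    channel: str = "other"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3-D, got shape {self.data.shape}")
        self.voxel_size_um = _check_voxel_size(self.voxel_size_um)
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size_um))


@dataclasses.dataclass
class LabelMask:
    """Binary 3-D foreground mask aligned to an IntensityVolume."""

    data: np.ndarray
    voxel_size_um: Triple = (2.0, 2.0, 2.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3-D, got shape {self.data.shape}")
        if self.data.dtype != bool:
            vals = np.unique(self.data)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("mask values must be binary")
            self.data = self.data.astype(bool)
        self.voxel_size_um = _check_voxel_size(self.voxel_size_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size_um))


@dataclasses.dataclass
class CellRecord:
    """One detected nucleus: centroid, volume and per-gene expression."""

    cell_id: int
    centroid_vox: tuple[float, float, float]  # (z, y, x), voxel units
    centroid_um: tuple[float, float, float]   # (z, y, x), micrometers
    volume_um3: float
    genes: Dict[str, bool] = dataclasses.field(
        default_factory=lambda: {"vglut1": False, "vgat": False})


# -- volumes ----------------------------------------------------------------

def _payload_3d(arr: np.ndarray, path) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D payload, got shape {arr.shape}")
    return arr


def read_volume(path: str | Path, voxel_size_um: Sequence[float] = (2.0, 2.0, 2.0),
                channel: str = "other", dataset: str = "volume") -> IntensityVolume:
    """Read a multi-page TIFF, HDF5 dataset or Zarr array as a volume."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile
        arr = tifffile.imread(path)
    elif suffix in (".h5", ".hdf5"):
        import h5py
        with h5py.File(path, "r") as fh:
            key = dataset if dataset in fh else next(iter(fh))
            arr = fh[key][...]
    elif suffix == ".zarr":
        import zarr
        node = zarr.open(str(path), mode="r")
        arr = node[dataset][...] if hasattr(node, "keys") else node[...]
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    arr = _payload_3d(arr, path)
    # widen to a common numeric type so downstream math never overflows
    data = arr.astype(np.float64, copy=False)
    if np.any(data < 0):
        raise ValueError(f"{path}: negative intensities")
    return IntensityVolume(data, tuple(voxel_size_um), channel)


def write_volume(volume: IntensityVolume | LabelMask, path: str | Path,
                 dataset: str = "volume") -> None:
    path = Path(path)
    data = volume.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile
        # one z-plane per page; never interpret small axes as color channels
        tifffile.imwrite(path, data, photometric="minisblack")
    elif suffix in (".h5", ".hdf5"):
        import h5py
        with h5py.File(path, "w") as fh:
            fh.create_dataset(dataset, data=data)
    elif suffix == ".zarr":
        import zarr
        root = zarr.open(str(path), mode="w")
        root.create_array(dataset, shape=data.shape, dtype=data.dtype)
        root[dataset][...] = data
    else:
        raise ValueError(f"unsupported volume format: {path.name}")


def read_mask(path: str | Path, voxel_size_um: Sequence[float] = (2.0, 2.0, 2.0),
              dataset: str = "volume") -> LabelMask:
    vol = read_volume(path, voxel_size_um, dataset=dataset)
    return LabelMask(vol.data > 0, vol.voxel_size_um)


# -- cell tables -------------------------------------------------------------

def write_cell_table(cells: List[CellRecord], path: str | Path) -> None:
    """CSV with one row per record; empty input yields a header-only file."""
    rows = [{
        "cell_id": c.cell_id,
        "z_um": c.centroid_um[0],
        "y_um": c.centroid_um[1],
        "x_um": c.centroid_um[2],
        "volume_um3": c.volume_um3,
        "vglut1": int(c.genes.get("vglut1", False)),
        "vgat": int(c.genes.get("vgat", False)),
    } for c in cells]
    df = pd.DataFrame(rows, columns=CELL_TABLE_COLUMNS)
    df.to_csv(path, index=False)


def read_cell_table(path: str | Path,
                    voxel_size_um: Sequence[float] | None = None) -> List[CellRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(CELL_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        um = (float(row.z_um), float(row.y_um), float(row.x_um))
        if voxel_size_um is not None:
            vs = _check_voxel_size(voxel_size_um)
            vox = tuple(u / s for u, s in zip(um, vs))
        else:
            vox = um
        records.append(CellRecord(
            cell_id=int(row.cell_id), centroid_vox=vox, centroid_um=um,
            volume_um3=float(row.volume_um3),
            genes={"vglut1": bool(row.vglut1), "vgat": bool(row.vgat)}))
    return records
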