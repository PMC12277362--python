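# vusmamba

Self-supervised cell-type mapping for thick, multi-FISH-labeled brain-slice
volumes, built around **VUSMamba**, a 3-D U-shaped selective-state-space
(Mamba-style) segmentation network — implemented from scratch in
NumPy/Numba with a custom reverse-mode autodiff engine (no deep-learning
framework required).

## The science

Multiplexed FISH on thick (≈300 µm) cleared brain slices yields volumetric
images where a Hoechst channel stains all nuclei and marker channels
(Vglut1, Vgat) label excitatory and inhibitory neurons. Mapping cell types
then requires: segmenting nuclei and marker signal in 3-D, detecting
individual cells, calling genes per cell, and summarizing the spatial
organization — densities per region, excitatory/inhibitory proportions, and
the *molecular boundary* where one population gives way to another.

The package implements that full pipeline:

- **`vusmamba.synthetic`** — phantom generator with complete ground truth:
  ellipsoidal nuclei (semi-axes 3–5 µm at 2 µm voxels), perinuclear marker
  shells, realistic contrast and noise, plus two-population boundary
  phantoms with a known boundary curve.
- **`vusmamba.preprocessing`** — fixed-window intensity normalization
  (112, 1000) and overlapping tiling.
- **`vusmamba.model`** — the VUSMamba network: 4×4×4 patch embedding,
  encoder depths (2, 2, 6, 2) with patch merging, four-direction 3-D
  selective scan (S6) in every VSS block, skip-connected decoder
  (2, 2, 2) and a voxel-wise two-class head.
- **`vusmamba.pretrain`** — three-task self-supervised pretraining:
  rotation prediction, NT-Xent contrastive encoding (temperature 0.1) and
  volumetric patch-exchange recovery, combined with weights (1, 1, 1).
- **`vusmamba.segmentation`** — fine-tuning with cross-entropy + soft Dice,
  AdamW (lr 1e-3, weight decay 0.1, warmup-cosine), tiled inference, and
  DSC / Jaccard / sensitivity metrics.
- **`vusmamba.celltype`** — 26-connected component detection, volume
  validity window 110–540 µm³, intersection-based gene calling, region
  densities and proportions.
- **`vusmamba.boundary`** — neighborhood enrichment scores, two-Gaussian
  equal-posterior boundary estimation, curve comparison (MAE, enclosed
  area, Pearson) and signed normal deviations.

See [`docs/methods.md`](docs/methods.md) for the algorithms, parameter
choices and limitations.

## Worked example

```python
import numpy as np
from vusmamba.synthetic import PhantomSpec, generate_phantom, generate_boundary_phantom
from vusmamba.celltype import detect_cells, summarize_region
from vusmamba.boundary import BoundaryCurve, estimate_boundary, compare_curves

# 1. Simulate a small multi-FISH phantom (2 um voxels) with known truth.
spec = PhantomSpec(shape=(24, 96, 96), n_cells=50, seed=42)
ph = generate_phantom(spec)
print("channels:", sorted(ph.channels))
print("ground-truth cells:", len(ph.gt_cells))

# 2. Detect cells from the masks and call marker genes.
cells = detect_cells(
    ph.gt_masks["hoechst"],
    {"vglut1": ph.gt_masks["vglut1"], "vgat": ph.gt_masks["vgat"]},
    voxel_size_um=spec.voxel_size_um)
print("detected valid cells:", len(cells))
s = summarize_region(cells, np.ones(spec.shape, bool),
                     voxel_size_um=spec.voxel_size_um)
print(f"total density: {s.n_cells / s.region_volume_mm3:.0f} cells/mm^3")
print(f"vglut1-only proportion: {s.proportions['vglut1_only']:.2f}")

# 3. Recover the molecular boundary between the two populations.
def sine(y):
    return 200.0 + 80.0 * np.sin(np.pi * np.asarray(y, float) / 1024.0)

bp = generate_boundary_phantom(shape=(16, 256, 256), boundary=sine,
                               n_per_side=250, seed=7)
curve = estimate_boundary(bp.gt_cells, r_um=50.0)
truth = BoundaryCurve(bp.truth_boundary.dv_um, bp.truth_boundary.x_um)
m = compare_curves(curve, truth)
print(f"boundary MAE: {m['mae']:.1f} um, Pearson: {m['pearson']:.3f}")
```

Output:

```
channels: ['hoechst', 'vgat', 'vglut1']
ground-truth cells: 50
detected valid cells: 50
total density: 28257 cells/mm^3
vglut1-only proportion: 0.40
boundary MAE: 8.6 um, Pearson: 0.991
```

Cell detection recovers all 50 cells exactly (the phantom guarantees
non-touching nuclei, so the connected-component stage is exact by
construction), and the estimated boundary tracks the true sinusoidal curve
to within about one cell diameter.

## Command line

A `vusmamba` console script exposes the pipeline stages:

```bash
vusmamba simulate --seed 0 --n-cells 300 --shape 32 128 128 --out data/
vusmamba pretrain  --data data/ --out ckpt/pretrained.npz --epochs 3
vusmamba finetune  --data data/ --init ckpt/pretrained.npz --out ckpt/model.npz
vusmamba segment   --checkpoint ckpt/model.npz --volume data/hoechst.tif --out pred.tif
vusmamba evaluate  --pred pred.tif --gt data/gt_hoechst.tif
vusmamba celltype  --hoechst pred.tif --vglut1 ... --vgat ... --out cells.csv
vusmamba boundary  --cells cells.csv --out boundary/
```

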