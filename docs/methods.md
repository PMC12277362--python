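# Methods

This document describes the models, algorithms and numerical choices
implemented in `vusmamba`, the assumptions behind the synthetic data
generator, and the known limitations. Interfaces are described in the
README; this file explains *what is computed and why*.

## 1. Problem setting

The package targets cell-type mapping in thick (hundreds of micrometers)
brain-slice volumes imaged with multiplexed FISH: a Hoechst channel labels
all nuclei, and marker channels (here Vglut1 and Vgat) label excitatory and
inhibitory neurons. The pipeline is:

1. intensity normalization and tiling,
2. self-supervised pretraining of a 3-D segmentation network on unlabeled
   tiles,
3. supervised fine-tuning on a small annotated set,
4. tiled inference and voxel-overlap evaluation,
5. connected-component cell detection, volume filtering and gene calling,
6. region statistics and molecular boundary estimation between the two
   marker-defined populations.

## 2. Network: U-shaped visual state-space model

`VUSMamba` is a 3-D U-shaped encoder–decoder whose mixing primitive is a
selective state-space (S6) scan rather than attention or large convolutions.

**Patch embedding.** The input volume (D, H, W) is split into 4×4×4 patches;
each patch is linearly projected to `base_channels` (C) features and layer-
normalized, giving a (D/4, H/4, W/4, C) token grid.

**Encoder.** Four stages of VSS blocks with depths (2, 2, 6, 2). Between
stages, patch merging concatenates each 2×2×2 neighborhood (8C features)
and linearly projects to 2C, halving the grid and doubling the channels:
C → 2C → 4C → 8C.

**VSS block.** LayerNorm → linear expansion C → 2C → depthwise 3×3×3
convolution → SiLU → SS3D scan → LayerNorm → linear projection back to C,
with a residual connection around the whole block.

**SS3D.** The feature volume is flattened along four scan orders (forward
and reverse raster order over (D, H, W), and forward/reverse over the
transposed (W, H, D) axis order). Each order is processed by an independent
S6 scan and the four outputs are summed. The S6 recurrence per channel is

    h_k = Ā h_{k-1} + B̄ v_k,      y_k = C_k h_k + D v_k

with zeroth-order-hold discretization Ā = exp(ΔA) and the first-order
approximation B̄ ≈ ΔB (error O(Δ²), verified by a Δ-halving test). A is
diagonal, initialized A_n = −(n+1) and parameterized as −exp(A_log) so it
stays negative (stable: |exp(ΔA)| < 1 for Δ > 0). Δ is per token and per
channel, softplus of a learned linear map with bias initialized so softplus
lands log-uniformly in [1e−3, 0.1]. B and C are per-token linear
projections of the input.

**Decoder.** Three stages (depths 2, 2, 2); each stage patch-expands by 2×
(channels halve), concatenates the matching encoder skip and fuses with a
linear layer, then applies VSS blocks. A final 4× patch expansion returns
to voxel resolution (C/4 channels per voxel) and a 1×1×1 linear head
produces 2 class scores per voxel.

**Head calibration.** Before fine-tuning, the head weights are zeroed and
the foreground bias set to logit of the empirical foreground prior of the
training masks. This is the standard prior-matched initialization for
class-imbalanced dense prediction; without it the early optimization budget
is spent unlearning an arbitrary random prior.

## 3. Differentiation and optimization

No deep-learning framework is used. The package ships a minimal
reverse-mode autodiff engine over float64 NumPy arrays (`vusmamba.autodiff`)
with a hand-derived adjoint for the S6 scan (`vusmamba.scan`, forward and
backward recurrences JIT-compiled with numba). Gradients of every operator
are tested against central differences.

Training uses decoupled AdamW (lr 1e−3, weight decay 0.1) under a
warmup-cosine schedule (10% linear warmup). The schedule horizon is
configurable: by default it spans the executed run; setting
`schedule_epochs` runs a shorter budget as a *truncation* of a longer
recipe, preserving the learning-rate trajectory of the full recipe instead
of compressing it. Batch size is 1 volume (no batch dimension anywhere).

## 4. Self-supervised pretraining

Three pretext tasks share the encoder:

- **Rotation prediction**: the tile is rotated by r·90° about the axial
  axis, r ∈ {0, 1, 2, 3}; a linear head on the pooled bottleneck predicts r
  (cross-entropy).
- **Contrastive encoding**: NT-Xent with cosine similarity at temperature
  0.1. Positives are two views of the same tile (its rotated and
  patch-exchanged versions); negatives are views of other tiles in the same
  accumulation chunk. Because the recipe is batch-size-1, views are
  accumulated over `batch_pairs` tiles (default 4) before one optimizer
  step, otherwise no negatives exist.
- **Recovery**: `n_exchanges` disjoint cubic patches (side
  `exchange_patch`) are swapped pairwise within the tile and the decoder
  must reconstruct the original (mean squared error). Defaults (30³, 6
  swaps) suit (64, 256, 256) tiles; for small tiles the corruption is scaled
  to preserve the corrupted-volume fraction (e.g. 2 swaps of 14³ on
  (32, 64, 64), ≈ 4%).

The combined loss is λ₁·l_rot + λ₂·l_con + λ₃·l_rec with λ = (1, 1, 1).

## 5. Fine-tuning, inference and metrics

Fine-tuning minimizes cross-entropy plus soft Dice on the foreground
probability. The best epoch by validation DSC is kept. Inference tiles the
volume (with overlap), computes softmax foreground probabilities per tile,
mean-blends overlaps, and binarizes at 0.5. Metrics:

    DSC = 2TP / (2TP + FP + FN),  Jc = TP / (TP + FP + FN),
    Sst = TP / (TP + FN)

(the identity DSC = 2Jc/(1+Jc) is enforced by tests).

## 6. Cell typing

Nuclei are 26-connected components of the Hoechst foreground mask.
Components with voxelized volume in [110, 540] µm³ (inclusive) are valid
cells. A cell is positive for a marker gene iff its nucleus voxels
intersect the marker's foreground mask in at least one voxel. Region
summaries report counts, densities per mm³ (count divided by the region
mask volume) and proportions of the Vglut1-only / Vgat-only /
double-positive populations. Proportions are taken relative to **all**
cells assigned to the region (by centroid voxel), so they sum to 1 exactly
when every cell expresses at least one marker.

## 7. Molecular boundary estimation

Cells in a 32 µm axial slab are collapsed to the (DV, ML) plane. The
package's concrete enrichment-score definition is

    E_i = (n_vglut1 − n_vgat) / (n_vglut1 + n_vgat)

over neighbors within 50 µm of cell i (self included), so E saturates at
±1 deep inside either population. Cells are split by the sign of E (ties to
the positive group), a full-covariance 2-D Gaussian is fitted per group by
maximum likelihood with mixture weights proportional to group sizes, and
the boundary is the equal-posterior locus: at each DV sample the condition
is a quadratic in the ML coordinate and the root lying between the two
conditional means is taken. Curves are compared on a common DV grid by MAE,
the enclosed area (trapezoidal integral of |difference|, reported as AUC)
and Pearson correlation; for constant curves (zero variance) the Pearson
value is 1 for identical curves and NaN otherwise, with a `constant_curve`
flag. Signed deviations along one curve's normals use central-difference
tangents and exact segment intersection, falling back (flagged) to the
nearest vertex when the normal misses every segment.

With equal group covariances the equal-posterior locus reduces to the
linear-discriminant hyperplane; this closed form is used as a test oracle.
A single boundary of the two-Gaussian model is a conic section, so only
boundaries that are graph-like and at most conic-shaped within the window
are recoverable. The bundled sinusoidal test scenario uses a monotone
(quarter-period) sine, which is well approximated by a conic over the
field of view; full-period oscillations are outside this model class and
would require a per-DV-window fit.

## 8. Synthetic phantoms

The generator (`vusmamba.synthetic`) produces volumes with known ground
truth at 2 µm isotropic voxels:

- **Nuclei**: axis-aligned ellipsoids, semi-axes uniform in [3.0, 5.0] µm,
  chosen so voxelized volumes (113–524 µm³) fall inside the downstream
  validity window [110, 540] µm³. Placement is rejection sampling with a
  conservative sphere margin so no two nuclei or perinuclear shells touch
  (a `PackingError` reports the achieved count when the request is
  infeasible).
- **Markers**: flagged cells carry a perinuclear shell (2-voxel dilation of
  the nucleus minus a 1-voxel erosion), which overlaps the outermost
  nucleus voxels so the non-empty-intersection gene rule applies. Flags are
  drawn per cell (defaults: Vglut1-only 0.45, Vgat-only 0.35, double 0.10,
  neither 0.10).
- **Intensities**: Gaussian-blurred masks (σ = 1 µm) scaled to a foreground
  mean of 800 over a background of 150, plus N(0, 20) noise, clipped at 0.
  These land in the fixed normalization window (112, 1000).
- **Boundary phantoms**: two populations labeled by the side of a caller-
  supplied curve x = f(y), with optional random flips inside a mixing band;
  the sampled truth curve is stored for recovery tests.

**Realism and limits.** The phantom reproduces the aspects the pipeline is
sensitive to — object scale relative to voxel size, valid-volume range,
marker/nucleus adjacency, contrast and noise floor — but not tissue-level
nuisance structure: no intensity inhomogeneity or vignetting, no touching
or overlapping nuclei (so the connected-component stage is exact by
construction), ellipsoidal rather than irregular nuclei, and spatially
homogeneous cell density except in boundary phantoms. Consequently,
segmentation and cell-typing scores on phantoms are upper bounds on
real-data performance, and the cell-typing acceptance checks exactness of
the *implementation*, not robustness of the *method*.

The training scenario uses 1,600 cells in a (32, 256, 320)-voxel phantom
(≈ 7.6·10⁴ cells/mm³), a density chosen to reflect cell-dense midbrain
tissue; adult mouse brain total cell density is of order 10⁵/mm³.

## 9. Numerical choices

- All tensors are float64; determinism is exact for a fixed seed on CPU
  (no threading nonreproducibility in the training path).
- The scan adjoint recomputes nothing: the forward stores the state
  sequence and the backward runs the adjoint recurrence in reverse.
- `s6_discretize` uses `scipy.linalg.expm` for full matrices and elementwise
  `exp` for diagonal A. Δ must be positive.
- Normalization maps the fixed window (112, 1000) affinely to [0, 1] with
  clipping.
- Tiled inference shifts edge tiles inward so every voxel is covered;
  overlapping predictions are averaged.
- Checkpoints are a `.npz` of named parameters plus a YAML sidecar with the
  architecture configuration; loading validates shapes.

## 10. Limitations

- Desk-scale only: the reference training scenario (tiny model, C=8,
  N=4, 20 fine-tuning epochs on 16 tiles) runs in minutes on one CPU core
  but is far below the scale of a real training run; reported scores apply
  to the bundled phantoms, not to real VISoR/multi-FISH data.
- The recovery head shares the decoder; no separate reconstruction decoder
  is implemented.
- The boundary model is a two-component Gaussian mixture per slab: one
  conic boundary per field of view, no uncertainty estimates.
- Marker segmentation in the acceptance pipeline uses ground-truth masks to
  isolate the cell-typing logic; end-to-end marker segmentation uses the
  same network per channel but is exercised only at smoke-test scale.
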