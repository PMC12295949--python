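# Methods

This note records what the package computes, the conventions it commits
to, and the choices made where the design space was genuinely open.

## 2.5D input construction

A CT volume is an (H, W, D) array in Hounsfield units with per-axis voxel
spacing in mm; slice index runs over the third axis, 0-based. The model
input for center slice *t* is the channel-first stack of the *n* slices
`t - ⌊n/2⌋ … t + ⌊n/2⌋` (*n* odd; default 3). Channels that would fall
outside `[0, D)` are all-zero planes — zero is the minimum of the
normalized intensity scale, so padding is "empty tissue". Supervision is
the mask of the **center slice only**.

Preprocessing order is window → crop → equalize → normalize, applied per
slice:

1. **HU window**: clamp to `[-200, 200]` HU (default). This symmetric
   soft-tissue window brackets liver parenchyma and lesions; the bounds
   are configuration.
2. **Center crop** to 448×448 (default) to trim air background. When the
   margin is odd the extra pixel goes to the high-index side — an
   arbitrary but fixed, testable convention. Inference pads predictions
   back to the original in-plane size with zeros.
3. **Histogram equalization** (optional, default on): global, per slice,
   256 bins spanning the HU window; each pixel maps to the empirical CDF
   of its bin. This is monotone in input rank, fixes constant slices, and
   stretches the narrow liver/tumor intensity band. Equalizing after the
   crop means the histogram reflects the anatomy-centered window rather
   than the air border; this ordering is a convention, not a constraint.
4. **Min–max normalization** to [0, 1] per slice; an all-constant slice
   maps to zeros to avoid 0/0.

Tumor-slice filtering (keeping only slices with at least one foreground
voxel) is a **training-set** operation; inference always covers every
slice. Filtering is evaluated on the cropped mask, so a slice whose tumor
lies entirely in the cropped-away border is dropped consistently with its
(empty) supervision target.

## Architecture

`RISUNet` is a five-level encoder–decoder. Encoder level *i* applies a
Res-Inception-SE (RIS) block and a 2×2 max-pool; the bottleneck counts as
the fifth level (four poolings, so H and W must be divisible by 16).
Decoder levels upsample with a 2×2 stride-2 transposed convolution,
concatenate the matching encoder feature map (skip connection), and apply
a RIS block. A final 1×1 convolution + sigmoid yields the per-pixel tumor
probability for the center slice.

Inside a RIS block (all convolutions stride 1, same padding):

* **F1** = 1×1 conv of the input — pointwise features.
* **F2** = 3×3 conv of F1 — local detail.
* **F3** = two further 3×3 convs on F2. Three stacked 3×3 kernels give a
  7×7 receptive field at the F3 tap (verified in the tests by a
  gradient-support probe) for a fraction of a 7×7 kernel's weights.
* **F4** = 3×3 max-pool (stride 1, same padding) on F3 followed by a 3×3
  conv — widens the receptive field again without changing resolution.
  The composition of this branch is the main architectural judgment call
  in the design; pool-then-convolve was chosen as the smallest "multiple
  convolution and pooling" combination that preserves shape.
* The four branches are concatenated (widths are an even split of the
  block's output width, remainder to F1) and fused by a 1×1 conv.
* **Squeeze-and-excitation**: global average pool to a per-channel
  descriptor, bottleneck `C → max(C/r, 1) → C` with ReLU then sigmoid
  (r = 16 default), output scaled per channel.
* **Residual**: a 1×1 projection of the block input is added to the
  attended map.

Every convolution in the branch/fuse path is conv → batch norm → ReLU
(conv bias omitted as redundant under the BN shift); the residual
projection is a plain biased 1×1 conv. Weights are Kaiming-uniform from a
seeded generator; biases zero. The SE squeeze layer deviates from this:
its weights are damped (×0.25) and its bias initialized to 1.0 so the gate
starts active and near-uniform — with symmetric init a width-1 bottleneck
ReLU would be dead at initialization about half the time, silencing the
attention path and its gradients.

**Channel plan.** Widths double per level from a base width. The frozen
default plan is `(77, 154, 308, 616, 1226)`: base 77, with the bottleneck
nudged from 1232 to 1226 so the default 2.5D configuration lands exactly
on the 15.02 M trainable-parameter reference budget (base width alone
moves the count in ~0.4 M jumps, too coarse to hit the budget). The count
is a pure function of the configuration and is verified against an
independent layer-by-layer arithmetic sum in the tests.

The n = 1 configuration is the same network operating as a plain 2D model.

## Objective

`L = α·L_Dice + β·L_BCE` with α = β = 1 by default; the weights are
exposed in configuration, and nothing in the ablation evidence available
to us disambiguates a better pair. Soft Dice is computed over the whole
batch (not per sample) with smoothing constant 1e-5, which keeps empty
target batches finite and stable; BCE is the mean over voxels with
probabilities clamped to `[1e-7, 1 - 1e-7]`. The plain-sum Dice
denominator (no squares, no per-class averaging) is used.

## Metrics

Per case, with ground truth A and prediction B:

* `DPC = 2|A∩B| / (|A|+|B|)`; both masks empty → 1.
* `VOE = 1 − |A∩B| / |A∪B|`; empty union → 0.
* `RAVD = ||B|−|A|| / |A|` — the **absolute** convention, so the value is
  a nonnegative "smaller is better" quantity; undefined for empty A.
* `ASSD` / `RMSD`: mean / root-mean-square of the pooled symmetric
  nearest-surface distances in mm.

Surface voxels are foreground voxels with a background 6-neighbor, the
volume boundary counting as background (so cavity walls and clipped faces
are surface). Distances use an anisotropic Euclidean distance transform
with the voxel spacing; the tests verify equivalence with an all-pairs
brute force to 1e-9 mm on hundreds of random mask pairs. Surface metrics
are undefined when either mask is empty; case-level evaluation reports
them as missing and the summary excludes them. Results are aggregated
per volume and then averaged (the usual convention for case-level CT
reporting).

## Synthetic phantoms

Each phantom is a smoothly warped ellipsoidal "liver" (semi-axes drawn
per case) in a darker background, with 1–3 spherical "tumors" placed
fully inside the liver by rejection sampling against the liver's interior
distance map. Per-region voxel intensities are drawn independently —
background −100±20 HU, liver 60±10 HU, tumor 45±10 HU — then Gaussian
smoothed (σ = 1 voxel, a partial-volume stand-in) and overlaid with 5 HU
additive noise. Default geometry is 64×64×24 voxels at 1×1×2.5 mm. The
15 HU liver-tumor contrast emulates the low-contrast regime that makes
real lesions hard; it is configurable down to harder settings.

Each case's random stream is derived from (master seed, case index), so
any case regenerates in isolation from the manifest. Splits use seeded
shuffling with largest-remainder allocation of the normalized fractions
(default 8:2:2 — over 12 cases: 8/2/2).

What the phantoms do **not** model: anatomy (vessels, adjacent organs,
lobes), acquisition physics (beam hardening, streaks, dose noise
correlation), irregular lesion shapes, or 512×512 full-field geometry.
Passing the end-to-end tests therefore demonstrates that the pipeline is
correct and trainable, not that it reaches clinical accuracy on real CT.

## Training protocol

Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) at learning rate 0.003, batch size
8, 150 epochs by default, global seed 39 covering initialization, data
order and augmentation. Augmentation: random crop of a uniform
[0.8, 1.0] side fraction resized back (bilinear for images,
nearest-neighbor for masks), then horizontal/vertical flips with
probability 0.5 each — identical transforms for all channels of a stack
and its mask; validation data are never augmented. The epoch with the
best validation Dice (global Dice over pooled validation voxels) is the
retained checkpoint. Predictions binarize at probability 0.5. Non-finite
loss aborts with a diagnostic rather than training through NaNs.

The slice-count harness retrains the same configuration for each n in
{1, 3, 5, 7} under identical seeds and reports the five metrics on the
shared test split as one CSV row per n. On phantoms it demonstrates the
harness, not which n is best — that ranking is a property of real data.

## Numerical core

The network runs on a small reverse-mode autodiff engine over float64
NumPy arrays (`risunet.nn`): im2col convolutions, einsum-based 2×2
stride-2 transposed convolutions (patches are disjoint), argmax-routed
max-pool backwards, and batch norm with the standard whitening adjoint.
Float64 keeps gradient checks exact (central differences agree to ~1e-6)
and runs bit-reproducibly under a fixed seed on a single CPU. Checkpoints
are NumPy `.npz` archives with the model configuration embedded as JSON.

## Problem sizes in the test suite

The end-to-end tests train a base-width-8 model on the 12-phantom cohort
(64×64×24) for 200 optimizer steps — enough to overfit a fixed batch to a
hybrid loss below 0.05 and to reach ≥ 0.6 Dice on the held-out phantoms —
and exercise the full-budget model only for parameter counting and single
forward passes. These sizes are the package's own choice of a
minutes-scale, single-CPU regression target.

## Known limitations

* The exact composition of the F4 branch and the channel widths are the
  package's own calibrated choices; other splits reproducing the same
  parameter budget exist.
* Histogram equalization before/after cropping, the odd-margin crop rule,
  and the 0.5 binarization threshold are fixed conventions, all exposed
  in configuration where they plausibly matter.
* The NumPy engine is single-threaded-friendly and exact, not fast: the
  full 15 M-parameter model at 448×448 is practical for inference and
  parameter accounting, while large-scale training calls for a GPU
  framework implementing the same architecture.
* No DICOM assembly, no resampling to isotropic spacing, no multi-organ
  labels; liver (as opposed to tumor) masks are carried by the phantom
  generator but the training target is the tumor mask.
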