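# Methods

## Scope and design

`gamsunet` implements a 2D slice-wise segmentation pipeline for
ultra-high-field T1-weighted brain MRI: binary tissue masks (gray +
white matter, CSF excluded) predicted per axial slice and reassembled
into volumes. The package treats the architecture, the preprocessing
protocol, the evaluation/volumetry protocol, and the statistical
comparison machinery as first-class, independently testable components.

No deep-learning framework is used: `gamsunet.nn` is a compact NumPy
reverse-mode autodiff engine (im2col convolution with stride/dilation,
group normalization, 2×2 max pooling, half-pixel bilinear upsampling,
leaky ReLU/sigmoid, logit-space binary cross-entropy, Adam). It is
single-threaded and deterministic: for a fixed seed the full
train→predict→evaluate pipeline reproduces bitwise on CPU. Gradients of
every primitive are validated against central finite differences in the
test suite, and the assembled depth-2 network against an
abstraction-free float64 replay of the same arithmetic.

## Architecture and its frozen configuration

The network is a nested (UNet++-style) grid. Three block families:

- **RCU** — `y = LReLU(GN(Conv3×3,d( LReLU(GN(Conv3×3(x))) )) + proj(x))`
  with dilation d = 2 on the second convolution (padding = dilation, so
  spatial dims are preserved), GN groups = min(8, C) reduced to a
  divisor of C, leaky slope 0.01, convolution bias enabled, and a 1×1
  projection shortcut only when channel counts change.
- **SCSE** — `cSE(x) + sSE(x)`; the cSE bottleneck width is
  max(1, C/4); zero-initialized attention weights make the block the
  exact identity (each branch contributes 0.5·x), which the tests
  exploit as a closed-form anchor.
- **GatedSkip** — per-channel `σ(α)·x_skip + (1−σ(α))·Conv1×1(x_up)`.
  α is initialized to 0, so σ(α) = 0.5: the two sources start balanced
  equally. This reconciles two superficially conflicting descriptions of
  the initialization ("zero" for the parameter, "0.5" for the blend).

Topology: encoder column of one MSBlock (= 2 RCUs + SCSE) per level
with max pooling; every interior lattice node is a pure gated blend of
the previous same-level node against the projected, upsampled node one
level below (dense predecessors therefore enter through recursive
composition of binary gates rather than concatenation); the final
anti-diagonal adds one MSBlock per level; 1×1 conv + sigmoid head.
The 1×1 gate projection is applied before upsampling, where it is four
times cheaper.

Block multiplicity, the conv-free interior nodes, and the projection
placement were calibrated **once** against the published efficiency
table and then frozen in `src/gamsunet/configs/default.yaml`. With
depth 5 and widths (32, 64, 128, 256, 512) the frozen model has
14,773,690 parameters (14.77 M vs the tabulated 14.66 M, +0.8%) and a
metered forward cost of 20.52×10⁹ ops at 1×256×256 (vs 20.83, −1.5%).
An exact two-decimal match is not attainable in this design space: any
variant placing two full MSBlocks at the 512-wide level alone exceeds
the tabulated total, so the residual ~1–2% discrepancy is accepted and
documented rather than hidden. The reference plain nested U-Net
(two-conv nodes, BN, concatenation skips, bilinear upsampling) at the
same widths reproduces its tabulated 9.16 M exactly, anchoring the
width choice.

**FLOP convention.** The tabulated baseline costs match multiply-
accumulate counts (e.g. a 20-layer, 64-channel VDSR at 256² is 43.5
GMacs, exactly the tabulated 43.56), so `count_flops` uses the MAC
convention: one unit per conv/linear MAC, one unit per output element
for normalization, activations, pooling and interpolation; the
alternative 2-ops-per-MAC convention is available as
`convention="flop"`. The meter hooks into the executed primitives, so
the accounting cannot drift from the real graph.

## Preprocessing choices

- Axial axis = third voxel axis of the stored array; no canonical
  reorientation (assumption documented, matching slice-wise loading).
- Z-score normalization is **per volume**, computed before slicing, so
  test-time statistics are stable and independent of slice content.
- Images are resized bicubically to the working grid (default 256×256);
  masks with nearest neighbour — bicubic interpolation of a binary mask
  would destroy binarity, so this is a deliberate deviation from a
  literal reading of "each axial slice" being resized bicubically.
- Augmentation (training only): horizontal flip and rotation, each with
  probability 0.5, angle uniform in ±15°, image bilinear, mask nearest.
  Ranges and probabilities are unstated in the source protocol; these
  are conventional values, fixed once.
- Constant (zero-variance) volumes are rejected, not mapped to zeros.
- Every axial slice is emitted, including empty peripheral slices; the
  evaluation-side exclusion rule (below) is the only filter.

## Evaluation protocol

- **Dice**: 2|P∩G|/(|P|+|G|), with dice(∅,∅) := 1.0 — such slices are
  then removed by the exclusion rule anyway.
- **SSIM**: Wang et al. settings (11×11 Gaussian window, σ = 1.5,
  K1 = 0.01, K2 = 0.03, data range 1), computed on binarized masks,
  averaging only windows fully inside the image. Verified against both
  a brute-force sliding-window implementation and scikit-image to 1e-6.
  Both Dice and SSIM are computed on binarized predictions: the
  exact-0/1 filter is only meaningful on binarized inputs.
- **Exclusion rule**: slices with Dice or SSIM *exactly* 0 or 1 are
  flagged `included=false` — literal equality, no epsilon.
- **Volumetry**: nonzero voxels × (sx·Dx/T)(sy·Dy/T)·sz mm³ for a mask
  predicted on a T×T grid originating from a Dx×Dy slice — physical
  volume is invariant under the resize, which the tests assert.
  Volume agreement is the R² of OLS of predicted on reference volume.
- **Statistics**: Wilcoxon signed-rank (zeros discarded; exact 2ⁿ sign
  enumeration for n ≤ 12, which remains valid under ties; otherwise the
  continuity-corrected normal approximation with tie-corrected
  variance), Kruskal–Wallis with tie correction and χ² reference, and
  Shapiro–Wilk delegated to scipy. The first two are implemented from
  their rank formulas and are cross-checked against brute-force
  enumeration and scipy; null-calibration simulations confirm ~5%
  rejection at α = 0.05.

## Phantom generator

Each phantom is an ellipsoidal "brain" with a gray shell around a white
core (distinct intensities force the model to integrate spatial context
rather than threshold a single intensity), a CSF-intensity ventricle
excluded from the tissue mask, anisotropic spacing drawn per subject
from 0.6–0.8 mm, a multiplicative bias field (exponentiated zero-mean
second-order polynomial, ±20% amplitude) and additive Gaussian noise
(σ = 0.04 on a unit intensity scale, SNR ≈ 25). All draws come from a
per-subject seed derived from the master seed, so cohorts are
reproducible byte for byte.

What it does *not* emulate: MR physics (no Bloch/MP2RAGE contrast
model), partial-volume mixing at tissue boundaries, anatomy-shaped
cortical folding, motion or ghosting artifacts. Passing the recovery
study therefore demonstrates that the pipeline's mechanics (training,
inference, resize bookkeeping, filtering, volumetry) are correct and
that the network can learn a nontrivial segmentation — not that it
reaches any particular accuracy on real 9.4T anatomy.

## Desk-scale problem sizes

The recovery study (`gamsunet.experiments.phantom_recovery`) uses 12
phantoms of 64×64×32 voxels split 8/4, the reduced network (depth 3,
widths 8/16/32), slices processed on a 64×64 grid, and 8 training
epochs — the task converges well before the 20-epoch cap, and these
sizes keep a full three-seed replication to a few CPU-minutes. Training
hyperparameters (Adam lr 1e-4, weight decay 1e-5, batch 1, threshold
0.5) are the full-protocol values; Adam β = (0.9, 0.999), ε = 1e-8;
slices are shuffled across subjects each epoch; no validation split, no
schedule, no early stopping; final-epoch weights are used.

## Known limitations

- Evaluation-mode batch norm in the reference nested U-Net (running
  statistics only); it exists for accounting and comparison, not for
  serious training.
- The NumPy engine targets correctness and reproducibility, not speed;
  full-scale 256×256 training at depth 5 is possible but slow — the
  package's training claims are made at the reduced scale.
- `predict_volume` returns masks on the working grid with resize-
  corrected spacing rather than resampling back to the native grid;
  volumetry is exact under this convention, but voxel-wise overlay on
  the original volume requires an external resample.
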