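# Methods

## Problem and model

Dural hemorrhages appear on axial head CT as hyperdense peripheral
collections: subdural bleeds (SDH) track along the inner skull as thin
crescents, epidural bleeds (EDH) are lens-shaped (biconvex) because the
dura tethers them at sutures. The package trains one network to do both
tasks at once: delineate the lesion (binary mask) and name its type
(SDH vs EDH).

The network is a four-level U-shaped encoder–decoder.

* **Encoders E1–E4** are double Conv(3×3, stride 1)–BatchNorm–ReLU blocks
  with 2×2 max pooling between levels. Channel widths double per level:
  `base_filters` (default 64) → 128 → 256 → 512, bottleneck 1024. The
  first-level width and the bottleneck continue the published doubling
  pattern (the ladder 128/256/512 fixes the interior levels; 64 and 1024
  extend it consistently). `base_filters` scales the whole network
  uniformly, which is how the desk-scale tests run it.
* **CSR blocks** (Convolution + Squeeze-Excitation + Residual) recalibrate
  each encoder output and each skip path: a Conv-BN-ReLU block, an SE gate
  (global average pool → FC C→C/r with ReLU → FC C/r→C with sigmoid →
  channel-wise scale; r = 16, floored at width 1), and a direct additive
  skip from block input to output (1×1 projection when channels differ).
* **A full pre-activation residual unit** (BN→ReLU→conv, twice, plus an
  identity or 1×1-conv+BN shortcut) sits on the bottleneck. The published
  description of the shortcut term is ambiguous about where the activation
  sits; we use the standard full pre-activation reading, which keeps an
  unobstructed identity path (verified by the zeroed-branch gradient test).
* **Decoders D1–D4** upsample with 2×2 stride-2 transposed convolutions
  (channels halved), concatenate the CSR-processed encoder features of the
  matching scale, apply **spatial attention** — channel-wise max and mean
  maps, concatenated, a 7×7 convolution to one channel, sigmoid, broadcast
  multiply — and run a double conv. The insertion point (on the fused
  features, before the decoder convs) and the reading of the descriptor
  combination as channel concatenation follow the standard CBAM-style
  construction.
* **Heads**: a 1×1-conv + sigmoid segmentation head at full resolution
  (single channel: hemorrhage vs background; the type comes from the
  classifier), and a classification branch from the bottleneck —
  Conv-BN-LeakyReLU (slope 0.001), a 3×3 conv, global average pooling and
  a fully connected layer over {SDH, EDH}. The bottleneck tap uses the
  deepest, most semantic features. ReLU is used inside encoder/decoder
  convs, LeakyReLU only in the classifier branch.

### Objective

`M = focal(class) + δ · dice_loss(seg)` with δ = 1 by default. The focal
term is the canonical `−α(1−p_t)^γ log p_t` with γ = 2, α = 0.25 (the
published description names focal loss without parameters); the dice term
is `1 − soft dice` with smoothing ε = 1 in the loss (training stability)
and ε = 0 in reported metrics. Empty-vs-empty masks score dice/IoU 1 —
perfect agreement on absence — since the raw ratio is 0/0 there.

### Training loop

Adam at lr 1e-4, batch 16, 60 epochs by default; the learning rate is
multiplied by 0.5 after 10 epochs without monitored-loss improvement
(the published recipe gives the factor but not the trigger; we use
validation-loss plateau with configurable patience). Checkpoint selection
keeps the epoch with the best validation dice; when no validation set is
given the training dice is used. A stratified 10% validation carve-out is
the default in the estimator facade. Two batch-size values appear in the
source material (16 and 32); 16 is the default, configurable. All
shuffling, init and SMOTE randomness is seeded; repeated runs with one
seed are bit-identical.

## Autodiff engine

No deep-learning framework is part of the dependency set; the network runs
on a small reverse-mode autodiff engine (`duralseg.nn`) written on NumPy:
tape-based backprop over broadcast arithmetic, matmul, stride-1 same
convolution (im2col + BLAS matmul; input gradients via the flipped-kernel
convolution identity), non-overlapping 2×2 transposed convolution, 2×2 max
pooling, channel reductions and the usual nonlinearities. BatchNorm is
composed from primitives so its gradient comes from the tape rather than a
hand-derived formula. Every operation is validated against central finite
differences in the test suite; max-pool ties route gradient to the first
maximum (the subgradient convention).

## Phantom generator

The generator emulates the *structure* of an axial head-CT hemorrhage
dataset, not its radiometry: a bright skull ring (intensity ≈ 0.95), a
textured brain interior (≈ 0.40 ± 0.05 smooth texture), a hyperdense
lesion (≈ 0.70) hugging the inner skull, dark background (≈ 0.05), and
additive Gaussian noise (σ = 0.03), all on a [0,1] scale mimicking the
relative attenuation ordering of bone ≫ fresh blood > parenchyma > air.
SDH lesions are annular sectors (crescents, default 110° arc); EDH lesions
are disc–disc intersections (biconvex lenses, eccentricity 0.5). Lesion
area is matched to a target fraction of the brain area (default 6%) by
bisection on the shape thickness, so masks are exact by construction. The
two shape families are deliberately separable — a threshold on the
convex-hull-area/area ratio distinguishes them — giving the classifier a
learnable, clinically faithful signal.

What the phantoms do **not** model: Hounsfield calibration and windowing,
3-D partial-volume effects, skull-base anatomy, midline shift, mixed-density
chronic bleeds, and real inter-patient variability. Passing the phantom
suite therefore demonstrates that the pipeline's mechanics (shapes,
gradients, balancing, bookkeeping) and its learning dynamics are sound —
not clinical-grade performance on real CT.

## Preprocessing

Training path: resize (bilinear) → CLAHE → gamma → [0,1] normalization;
test path: resize + normalize only (the source material states the test
set was not enhanced). Masks always use nearest-neighbor resizing and stay
binary. CLAHE goes through scikit-image's `equalize_adapthist`; the config
keeps the familiar clip-factor convention (default 2.0, 8×8 tiles) and
converts to scikit-image's normalized scale by `clip / nbins` (nbins = 256).
A clip of 0 disables CLAHE entirely — note that a *large* clip limit does
not approach the identity (unclipped adaptive equalization is still AHE),
so "neutral parameters" means clip = 0 and γ = 1. Gamma defaults to 0.8
(mild brightening of dark parenchyma; only the qualitative effect of
γ ≶ 1 is stated in the source material).

## Balancing

Stratified split with per-class nearest-integer rounding of
`test_fraction × n` (56/173 at 20% → test 11/35, train 45/138, matching
the published table) via a seeded permutation. SMOTE interpolates flattened
pixel vectors between a sample and one of its k = 5 nearest same-class
neighbors (Euclidean default, cosine selectable; ties broken toward the
lower index), with u ~ U(0,1); the paired mask uses the same u and a 0.5
threshold, preserving spatial correspondence. Both classes are raised to a
common target (414 each in the published configuration — taken as
configuration, it is never derived), not classic minority-only SMOTE.
The record-level `synthetic` flag marks SMOTE-generated samples; phantom
slices enter the pipeline as its "real" data.

## Desk-scale study conditions

The trained-model checks run at 64×64 pixels with `base_filters = 8`
(ladder 8/16/32/64, bottleneck 128) and lr 1e-3: a 16-slice memorization
run (dice ≥ 0.9 within 200 epochs) and a 60-train/20-test phantom study
(held-out classification accuracy and AUC). These sizes were chosen once
as the smallest configuration at which the architecture's behavior —
learning both tasks jointly from the multi-task loss — is observable in
minutes on a single CPU; `scripts/acceptance.py` re-runs them end to end.

## Numerical choices and edge cases

* Softmax is max-shifted; focal loss clamps p_t at 1e-12 before the log.
* Undefined confusion-matrix ratios report NaN with a warning, never a
  silent 0. The standard precision TP/(TP+FP) is used.
* AUC is the trapezoidal integral of the ROC curve and equals the
  Mann–Whitney pairwise probability (ties = ½), which the tests verify
  against a brute-force pairwise count.
* Inputs to the network must be divisible by 16 (four poolings); this is
  validated, not padded.
* Max-pool and channel-max ties send gradient to the first maximum.
* Weights are He-initialized from a seeded generator; float32 throughout.

## Known limitations

* The engine is single-threaded NumPy: fine at desk scale, not meant for
  256×256 × 828-image training at full width (the published scale assumed
  GPU hardware).
* SMOTE operates in raw pixel space; with few, well-aligned phantoms this
  is meaningful, but on unregistered real CT interpolation can blur
  anatomy.
* The classifier head decides the lesion type globally per slice; slices
  containing both bleed types are outside the model's label space.
* The LR-plateau trigger, SE reduction ratio, focal parameters, δ, CLAHE
  and gamma defaults fill gaps in the published recipe and are all
  configurable.
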