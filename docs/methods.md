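# Methods

## Overview

The package couples two components: a fusion-based enhancement pipeline
that removes the red-bluish cast of H&E histopathology tiles, and a
dual-stream capsule network that classifies a tile from its raw and
enhanced versions simultaneously.  Everything runs on NumPy; forward and
backward passes of every layer are written by hand (im2col convolutions
backed by BLAS matmuls), which keeps the numerics fully inspectable and
removes any framework dependency.

## Enhancement pipeline

Stages, in order: channel compensation → two fusion inputs
(gamma-corrected, sharpened) → three weight maps per input → δ-normalized
weights → multi-scale fusion.

**Channel compensation.**  All three channels are compensated
simultaneously from the *original* channels and their means (the update
equations reference only unprimed quantities, so no sequential update is
implied): red and blue are pulled toward the green mean, green toward the
red mean, each term attenuated by (1 − channel) and gated by the partner
channel.  α defaults to 1.  When the three channel means coincide the
transform is exactly the identity.  Outputs are clipped to [0, 1].

**Gamma input.**  `v ↦ v^γ` with γ = 1.3 by default.  The source
description never fixes γ; 1.3 darkens midtones enough to re-spread the
histogram of the compensated tile without crushing shadows, and it is
config-exposed.

**Sharpened input.**  Normalized unsharp masking
S = (Φ + N{Φ − G∗Φ})/2, where G is a Gaussian at σ = 1.0 (window radius
2·ceil(2σ), reflected boundaries) and N is one global min–max stretch of
the three-channel difference field to [0, 1].  A single global stretch
(rather than per-channel) preserves the relative channel contrast of the
high-pass field.  Degenerate case: when the difference field is constant
(max = min) the stretch is undefined and N is taken to be the zero field,
so a flat image maps to Φ/2.  This is the only reading under which
min–max stretching is total, and it is deliberately prominent here.

**Weight maps.**  Per fusion input: (1) local contrast = |4-neighbour
Laplacian [[0,1,0],[1,−4,1],[0,1,0]] of the luminance|, reflected
boundaries; (2) frequency-tuned saliency = Euclidean CIELAB distance
between the image's mean color and the Gaussian-blurred pixel color, with
Lab scaled by 1/100 so the map shares the order of magnitude of the other
two (otherwise the δ regularizer would be negligible against Lab's 0–100
range); (3) saturation = per-pixel variance of (R, G, B) around the
luminance L = (R+G+B)/3, i.e. the *unrooted* form as the method prints
it; a `sqrt_saturation` switch (default off) selects the rooted form used
in the fusion literature the method builds on.  Luminance is the
unweighted channel mean throughout, since no weighting is specified.

**Normalization and fusion.**  W̄ₖ = (Wₖ + δ)/(ΣWₖ + Kδ), δ = 0.1 — an
exact algebraic identity guarantees the K maps sum to 1 at every pixel,
and δ keeps every input contributing where all raw weights vanish.
Fusion blends Laplacian pyramids of the inputs under Gaussian pyramids of
the weights, level by level, then collapses and clips.  Downsampling is
Gaussian blur (σ = 1) followed by decimation by 2 with ceiling sizes;
upsampling is bilinear resize to the exact finer-level shape, which keeps
odd-sized images well defined.  Pyramid depth defaults to the deepest
level whose min side is ≥ 8 px (3 levels for 50×50).  Because the
up/downsampling pair is not an exact adjoint, a Laplacian collapse
reconstructs the source only approximately; the round-trip error is
bounded at 0.02 max-abs in the tests (measured ~1e−3 on random fixtures,
the bound leaves headroom for adversarial content).  With one level the
multi-scale blend reduces exactly to the naive per-pixel blend.

## Capsule network

**Streams.**  CLB: four conventional 3×3, stride-1, same-padding, ReLU
convolutions with 64 filters (1792 + 3×36,928 parameters from 3 input
channels).  SCLB: four depthwise-separable equivalents (depthwise without
bias, pointwise with bias: 137 + 3×4736 parameters).  The separable
first-layer count of 137 is only consistent with a *single* input
channel, so the enhanced stream is reduced to luminance before SCLB; a
config switch allows 3 channels (283 parameters, flagged as deviating
from the reference counts).  Same-padding everywhere keeps the two
feature maps spatially aligned for the channel concatenation (CLB slice
first).

**Primary capsules.**  Each stream's 64-channel slice of the merged map
passes through its own 3×3 stride-2 capsule convolution (64 → 32·8 and
64 → 16·8 channels respectively), is globally average-pooled over space,
reshaped to capsule vectors and squashed — exactly 48 primary capsules of
dimension 8, 32 sourced from the raw stream and 16 from the enhanced one.
Pooling (rather than flattening the 25×25 spatial grid into ~30,000
spatial capsules) is this package's choice: it is the only construction
consistent with a fixed total of 48 capsules, and it keeps the routing
stage small.  The published "5120" primary-capsule parameter figure is
not reconstructable from any stated hyperparameters and is therefore not
a verification surface; the convolutional rows and the capsule counts
are.

**Routing.**  Votes û_{j|i} = W_ij uᵢ with per-pair 8×16 transforms;
logits start at zero (uniform couplings); each iteration computes
couplings by a softmax over parents, parent inputs s_j = Σᵢ c_ij û_{j|i},
outputs v_j = squash(s_j), and updates the logits by the inner-product
agreement on every iteration except the last (a final update would be
wasted).  Default 3 iterations, config-exposed.  The squash guard divides
by max(‖s‖, 1e−9) so the zero vector maps to zero and a unit vector maps
to norm exactly 1/2.

**Backward pass.**  Gradients flow through the weighted sum and the exact
squash Jacobian; the final coupling coefficients are treated as constants
of the backward pass.  With one routing iteration this is exact (the
couplings are the constant 1/J), which is how the full-model
finite-difference checks are run; with 3 iterations it is the standard
coupling-detached approximation, adequate for gradient descent because
couplings change slowly relative to the votes.

**Optimiser.**  Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8) at learning rate
1e−4, batch 32, 50 epochs by default — the reference training
hyperparameters.  Weights are float32 (He initialisation for
convolutions, σ = 0.1 normal for routing transforms); float64 is used for
gradient-check tests.

## Threefold margin loss

Three (m⁺, m⁻, λ) hinge pairs — (0.90, 0.10, 0.75), (0.80, 0.20, 0.55),
(0.70, 0.30, 0.35) — are evaluated on the *same* class-capsule norms and
summed, then summed over classes and averaged over the batch.  The
source's notation (v_k1, v_k2, v_k3) could be read as three distinct
capsule outputs, but the architecture has a single class-capsule layer,
so the single-output, three-margin reading is the only consistent one;
the alternative (per-stream heads) is noted here and not implemented.
Closed forms used as anchors: an all-zero true-class norm costs
Σ(mᶠ⁺)² = 1.94; a prediction with true norm ≥ 0.90 and wrong norms
≤ 0.10 costs 0.  The gradient w.r.t. the capsule vectors runs through
the norm (dL/dv = dL/d‖v‖ · v/‖v‖), with the zero vector assigned zero
subgradient.

## Evaluation harness

Per-class metrics are one-vs-rest: TP/FP/TN/FN per class from the
multiclass confusion matrix, then sensitivity = TP/(TP+FN), specificity,
precision, accuracy = (TP+TN)/total and F1 = TP/(TP+½(FP+FN)).  Per-class
"accuracy" is deliberately the one-vs-rest binary accuracy (the only
reading under which per-class accuracies can exceed the overall
multiclass accuracy).  Zero denominators return 0 with a warning.
ROC-AUC is computed one-vs-rest from the class-capsule norms via
scikit-learn (trapezoidal, tie-averaged).  The dataset split uses shares
18320 : 4580 : 2100 (73.28 / 18.32 / 8.40 %): train and validation sizes
are rounded to the nearest integer, test takes the remainder, so the
partition is disjoint and exhaustive; splitting is stratified by default
(a documented stabilising deviation from plain random splitting, with a
toggle) and falls back to unstratified when a class has fewer than two
members in the subset being split.  The k-fold harness wraps stratified
k-fold (k = 5 default) around a caller-supplied train-and-score callable.

## Synthetic data

Tiles are tinted backgrounds (green mean `cast_strength` = 0.15 below red
and blue, matching the H&E cast the compensation targets) plus a Poisson
number of Gaussian "nuclear" blobs with class-specific density (4, 10,
18, 30, 45 per 50×50 tile), radius ranges shrinking as density grows, a
dark-purple blob color, a small per-class background tint, and Gaussian
pixel noise (σ = 0.02).  This gives the enhancement pipeline a genuine
cast to correct and a classifier genuine structure (blob density/size and
tint) to learn.  It does **not** emulate gland morphology, stain-matrix
physics, scanner artifacts or inter-slide variability, so passing tests
demonstrate the correctness of the mechanisms — not clinical-grade
performance on real slides.

## Desk-scale training surrogate

Published-scale results (25,000 real tiles, 50 epochs) are out of scope
for a CPU desk run.  The stated surrogate is: 5 classes × 40 generated
50×50 tiles, 5 epochs, batch 8, learning rate 1e−4, seeded — about two
minutes on one CPU — asserting final training accuracy above the 0.2
chance level and a loss decrease from the first epoch to the last.  These
sizes are the package's own desk-scale profile and are also what
`scripts/acceptance.py` re-runs.

## Known limitations

- The coupling-detached routing backward is approximate for >1 iteration.
- Enhancement at native resolution and resizing at dataset-assembly time
  is assumed; the order is not specified by the source method.
- The Laplacian-pyramid round trip is approximate (bilinear upsampling is
  not the blur's adjoint); tolerance 0.02 max-abs.
- The spatial geometry between the last block layer and the primary
  capsules (stride-2 capsule convolution + global average pooling) is an
  assumption; alternatives (e.g. strided flattening) would change the
  primary-capsule parameter count but not the capsule totals.
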