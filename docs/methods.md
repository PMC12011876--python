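# Methods

## Problem setting

`amsmlp` segments a single plant leaf from an uncluttered ("pure")
background — a palm, a desktop, soil — in RGB photographs, producing a
per-pixel foreground probability map that is thresholded at 0.5 into a
binary mask. The intended use is plant-disease imaging pipelines, where an
accurate leaf silhouette is the precondition for downstream lesion
quantification.

## Model

The network is a five-level U-shaped encoder–decoder with three optional
modules layered on top of the plain backbone:

**Backbone.** Each encoder level applies two 3×3 conv + batch-norm + ReLU
bricks; 2×2 max-pooling connects levels, so channel widths double
(C₁, 2C₁, …, 16C₁) while spatial extents halve. The decoder mirrors this
with learned kernel-2/stride-2 transposed convolutions, concatenative skip
fusion, and two conv bricks per level; a 1×1 convolution plus sigmoid forms
the head. Convolutions feeding a batch-norm carry no bias term — the
normalization subtracts the batch mean, so such a bias receives an exactly
zero gradient and is dead weight.

**AM-MLP skip blocks.** Each skip connection splits its C channels into a
global and a local branch of C/2 channels each. Both branches apply a
channelwise feed-forward stack (FC → LayerNorm → FC → GELU, hidden width =
C/2 by default) and then three cascaded spatial-mixing stages. A stage
partitions the H×W map into non-overlapping p×p patches, giving axes
[batch, channel, patch_positions, within_patch], and applies one dense
(learned, biased) layer along a single axis:

* the **global** branch mixes the `patch_positions` axis — every location
  exchanges information with all locations sharing its within-patch offset,
  arbitrarily far away;
* the **local** branch mixes the `within_patch` axis — strictly confined to
  one block.

Patch sides are complementary, gᵢ·bᵢ = S per stage (S the level's spatial
extent); at S = 32 the defaults are grids [8, 4, 2] and blocks [4, 8, 16].
For other extents the rule g = [S/4, S/8, S/16], clamped at 2, extends the
same geometry. Each mixing stage carries a residual connection
(out = x + mix(x)); the cascade is three layers deep, and residuals keep it
trainable from a truncated-normal (σ = 0.02) initialization. A flag disables
them.

Branch fusion uses a squeeze-style channel attention: global average
pooling of the summed branch outputs, an FC (no bias) → batch-norm →
sigmoid bottleneck, then a second FC → sigmoid yielding α ∈ [0,1]^{C/2}.
The output is concat(α ⊙ F_global, (1−α) ⊙ F_local), restoring C channels.
A per-channel sigmoid on a single logit is exactly a two-way softmax over
(logit, 0), which is the only normalization compatible with the complement
constraint α′ = 1 − α. By default the gates multiply the post-cascade
branch outputs so the mixing stages sit on the output path;
`attention_applies_to="fc"` instead gates the pre-cascade projections.

**MPAM.** The multi-path aggregation mask module fuses all five encoder
scales into one foreground mask: levels 2–5 are reduced to width C₁ by 1×1
convolutions, brought to level-1 resolution by repeated ×2 bilinear steps,
summed with the level-1 features, concatenated with a sigmoid-gated copy of
the level-2 path and the raw level-1 features (3C₁ channels), collapsed by
a 3×3 brick and a 1×1 convolution + sigmoid, and finally average-pooled by
16 to level-5 resolution, where the deepest decoder stage consumes it.

**MCRD.** At the three deepest decoder junctions the skip feature is
refined before fusion: a soft mask m gates a foreground path conv(F ⊙ m)
and a background path conv(F ⊙ (1−m)); the two are concatenated and merged
by a third 3×3 brick. The mask comes from the deeper feature map (×2
bilinear upsample → 1×1 conv → sigmoid); at the deepest junction the MPAM
mask is used instead (upsampled ×2 from level-5 to the level-4 extent).
The mask head applies the convolution *before* the sigmoid so the mask is
guaranteed to lie in (0,1) and its complement is meaningful; the reverse
order is available behind `mcrd_literal_mask_order` for comparison. The
shallowest junction uses plain concatenative fusion.

**Ablation lattice.** `{use_am_mlp, use_mpam, use_mcrd}` reproduce the
five variants: all off (plain U-shaped baseline), AM-MLP only, AM-MLP +
MPAM, AM-MLP + MCRD, and all on.

## Training objective

L = λ·BCE + Dice, λ = 1 by default. BCE uses mean reduction so the loss
magnitude is independent of image resolution, with probabilities clipped to
[ε, 1−ε], ε = 1e−7, before the logarithm. The soft Dice term is
1 − 2Σfg / (Σf + Σg + 1e−7); two identically empty maps return 0 (a
degenerate perfect match) with a warning. Optimization is SGD with
momentum 0.9 and polynomial learning-rate decay (power 0.9) from a base
rate of 1e−3, batch size 2 — the reference training configuration; the
schedule (constant/step/poly) and momentum are configurable. The checkpoint
with the best validation foreground IoU is retained.

## Evaluation

Predictions are thresholded at 0.5 (ties count as foreground) and
accumulated into dataset-level pixel confusion counts. From these:
accuracy, recall, precision, specificity, F1 = 2PR·PP/(PR+PP), and
IoU = TP/(TP+FP+FN). mIoU is the mean of foreground IoU and background IoU
(TN/(TN+FP+FN)) computed from the same aggregated counts; per-image
averaging is available via per-sample counts but dataset aggregation is
the default, since the alternative definitions differ only in weighting.
Zero denominators yield NaN with a warning, never a silent 0.

## Synthetic scenes

The generator emulates single-leaf photographs on pure backgrounds so the
whole pipeline is testable without any private imagery. A leaf silhouette
is a superellipse r(θ) = R·(|cos θ|ⁿ + |sin θ|ⁿ)^(−1/n) with aspect ratio
0.55–0.9, sinusoidal edge serration (amplitude ≤ 0.10, 6–14 lobes), random
rotation, and a scale R chosen analytically (via the polar area integral)
to hit a target foreground fraction drawn from (0.15, 0.45). Backgrounds
are flat colors, linear gradients, palm-like or wood-like noise textures;
the leaf is filled with a shaded green gradient and up to four dark
elliptical lesion-like blemishes placed strictly inside the silhouette
(lesions never alter the mask). Means are separated by construction: leaf
green ≥ 0.58, background green ≤ ~0.45 before noise (σ ≈ 0.02), so
foreground and background differ by ≥ 0.1 in mean green.

What this does *not* emulate: multi-leaf scenes and occlusion, specular
highlights, shadows cast by the leaf, camera distortion, background
clutter, or the fine vein/serration detail of real leaves. Passing the
end-to-end gate therefore demonstrates that the implementation trains and
segments correctly — not that it reaches photographic-dataset accuracy.

## Scaled-down study protocol

The repository's end-to-end check trains the width-8 model on 200
synthetic 64×64 scenes (20 validation, 40 held-out test) for 15 epochs
with the reference optimizer settings, a problem size chosen so the full
study runs in minutes on a single CPU core. Gates: held-out foreground
IoU ≥ 0.90 and F1 ≥ 0.94, and the fully equipped model's best validation
IoU must not fall below the plain baseline's under identical data, seeds
and schedule. Reference datasets at 512×512 with tens of thousands of
gradient steps are out of scope here; only the directional ablation
ordering, not absolute published scores, is asserted.

## Numerical and design choices

* Pure-numpy reverse-mode autodiff underlies all layers; convolution is
  im2col + BLAS matmul, pooling/upsampling are reshape-based, and every
  operation's gradient is finite-difference tested.
* Data flows in float32; gradient-check tests run the same ops in float64.
* Max-pooling routes gradients to the first maximum on ties. Bilinear
  upsampling uses the align-corners-false convention.
* Batch-norm at inference uses running statistics (so batch-1 prediction is
  well defined); training mode uses batch statistics.
* Splits follow round-half-up for the 70% train share computed on exact
  rationals (0.7·1385 = 969.5 → 970), floor for the 10% validation share,
  remainder test.
* Polygon rasterization uses the pixel-center even-odd rule, 0-based,
  origin top-left. Mask resizing is nearest-neighbor (preserves binarity);
  image resizing is bilinear.
* Weight init: truncated normal (σ = 0.02, clipped at 2σ) for dense/mixing
  weights, He-normal for convolutions, zeros for biases, ones/zeros for
  normalization scales/shifts; a single seeded generator makes
  construction bitwise reproducible.
* Per-epoch shuffling is seeded by (run seed, epoch) and the optimizer
  velocity is checkpointed, so an interrupted run resumes on the identical
  trajectory.

## Known limitations

* One dense mixing matrix per stage is shared across channels (as in
  standard spatial-MLP mixers); channel-specific mixing would grow
  parameters quadratically.
* Training is single-threaded CPU numpy: fine at study scale, roughly two
  orders of magnitude slower than a GPU implementation at 512×512.
* The attention batch-norm sees very small batches (size 2 during
  training); its running statistics are correspondingly noisy.
* `mean_iou` aggregation conventions differ across the literature; both
  dataset-aggregated (default) and per-image variants are provided, and
  reported numbers should state which was used.
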