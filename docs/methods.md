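# Methods

## Problem and model family

The package segments grayscale thyroid ultrasound images into background
(0), gland (1) and nodule (2).  Four encoder–decoder architectures are
provided on one U-shaped skeleton: the classical U-Net baseline with
double 3×3 convolution blocks (depth 5, widths 64…1024), and three
variants that replace every conv block with a split-attention residual
block and add one extra top encoder/decoder level (depth 6, widths
32…1024) to strengthen extraction of edges and small nodules: SRU-Net
(blocks only), ASRU-Net (plus ASPP between encoder and decoder) and
DSRU-Net (plus DASPP).  The decoder mirrors the encoder level for level —
upsample ×2, concatenate the skip feature, apply the level's block — and
a final 1×1 convolution emits per-class logits at input resolution.  All
convolutions are padded ("same"), so inputs only need spatial dimensions
divisible by 2^(depth−1); the reference input size is 512×512 after
letterboxing.

Motivation for the two additions, quantified by the analysis module: one
element of the baseline's deepest encoder feature sees at most a 140×140
input region (receptive-field recurrence; glands and super-large nodules
can exceed this), and the shallowest features pass through only two
convolutions (valid-size arithmetic: 572 → 568 in the unpadded original;
512 → 512 here with padding).  ASPP/DASPP add global context at the
bottleneck; the split-attention blocks deepen shallow processing.

## Block definitions and chosen readings

**Split-attention residual block.**  Main path 1×1 conv → radix-split
grouped 3×3 conv → split attention → 1×1 conv, each conv followed by
batch normalization and ReLU; residual shortcut (identity, or 1×1 conv +
BN when shape changes).  Attention weights are softmax over the radix
axis of two 1×1 transforms of the globally pooled split-sum; the inner
width is `max(width·radix/reduction_factor, 32)` (reduction factor 4).
Cardinality is fixed at 1.  With radix 1 the softmax of a singleton is
exactly 1 and the block degenerates to a plain bottleneck residual.
Downsampling, when requested, is an average-pool after the first 1×1
conv and at the start of the shortcut, so every convolution in the
package is stride-1.  Defaults: radix 2.  The exact placement of
normalization/activation around the shortcut follows the standard
split-attention design, since only the block topology is otherwise
constrained.

**ASPP.**  Branches: 1×1 conv; 3×3 dilated convs at rates (1, 6, 12, 18)
— the DeepLab-v3 convention, configurable; optional global-average-pool
branch projected by 1×1 conv and broadcast back to H×W.  Branch width
defaults to in/4 (256 at reference width), fused by 1×1 conv to in/2
(512).  Dropout (0.5) is applied only on the fused pyramid output — the
DeepLab placement — so the U-Net baseline legitimately contains no
dropout.

**Deformable convolution.**  DCNv3-flavoured reading: a shared 3×3
weight over grouped channels (groups 4 when divisible, else the largest
divisor ≤ 4); one set of K = 9 per-location fractional offsets shared
across groups, predicted by a 3×3 conv; per-point modulation scalars
normalized as K·softmax(logits) over the K points, so they sum to the
constant K per location and zero logits give exactly 1 per point.
Samples are read by bilinear interpolation with zero outside the image.
Offset and modulation predictors are zero-initialized, so a fresh
deformable layer computes exactly a standard 3×3 convolution — this
both stabilizes early training and makes the degeneracy testable to
1e-5 against a dense-convolution oracle.  Softmax (rather than sigmoid)
modulation is the chosen reading where the normalization is not pinned
down.

**DASPP.**  ASPP with the dilation-1 branch replaced by a deformable
conv (+BN+ReLU) and one additional parallel deformable branch mapping
in → in/2 (1024 → 512 at reference width); all branch outputs are
concatenated and fused by a 1×1 conv to in/2.  With frozen-zero offsets
and uniform modulation DASPP equals the same structure with plain 3×3
convolutions, which is the oracle used in tests.

## Objective

`L_total = L_wce + L_dice`.

* `L_wce`: per-pixel terms `w[y]·(−log softmax(ŷ)[y])` with a
  weighted-mean reduction (sum of weighted terms divided by the sum of
  applied weights).  The printed form of this loss elsewhere normalizes
  by a batch-level weight sum that is inconsistent with the per-pixel
  numerator; the standard weighted-mean reduction of common toolkits is
  implemented instead, and class weights default to (1, 1, 1).
* `L_dice`: soft dice over all C classes including background,
  `1/N · Σ_n Σ_c (1 − (2·Σ y·p + ε)/(Σ y² + Σ p² + ε))` with pixel sums,
  softmax probabilities `p`, one-hot targets `y`, and ε = 1, which keeps
  classes absent from both target and prediction at a contribution of
  exactly 0 and makes perfect one-hot prediction score exactly 0.

## Training recipe and pipeline

AdamW with lr 1e-4 (constant; no schedule), decoupled weight decay 1e-2
(the optimizer's canonical default), batch size 8, 200 epochs at
reference scale; Kaiming-normal initialization for conv weights; zeros
for deformable offset/modulation predictors.  Inputs are letterboxed to
512×512: aspect-preserving resize (bilinear image / nearest mask; the
short side rounds half-up), symmetric zero fill with the odd pixel on
bottom/right — bit-visible and therefore fixed as stated; the stored
record makes the inverse mapping exact.  Augmentation applies each
transform independently at probability 0.5 with conservative
ultrasound-plausible ranges: brightness ±0.2, contrast ×[0.8, 1.25],
horizontal mirror, rotation ±15°, crop keeping ≥ 80 % per axis, stretch
×[0.9, 1.1]; geometric transforms act identically on image and mask,
fills are 0, images are clipped to [0, 1].  The train/validation split
is a seeded shuffle-then-cut (validation = the permutation's prefix, so
validation sets are nested across fractions); default fraction 0.1,
image-level.  After every epoch the validation mean foreground dice is
computed and the best checkpoint retained; the pipeline aborts with an
epoch/batch diagnostic if the loss becomes non-finite.  Training runs are
deterministic given the config seed (all randomness flows through
explicit NumPy generators).

Prediction letterboxes the input, takes the per-pixel argmax of the
logits, optionally removes small 8-connected components per foreground
class (minimum area defaulting to 0.1 % of the image; a largest-only
mode exists because the thyroid is one contiguous organ), inverts the
letterbox, and writes the native-resolution mask plus a contour overlay
(gland blue, nodule red).

## Metrics

One-vs-rest pixel counts per class feed SP, SE, PR, ACC, IoU and Dice.
Degenerate denominators (class absent from both truth and prediction)
score 1.0; an absent class that was predicted scores 0.0 through the
ordinary formulas.  The "mean" columns are, by default, macro averages
over images and then over the foreground classes {gland, nodule};
whether background is included is configurable rather than asserted,
and micro averaging (pool counts first) is also provided.  Metrics are
computed at the resolution the model saw (letterboxed), with the inverse
mapping available to score at native resolution instead.

## The numerical stack

No deep-learning framework is a dependency: `thyroseg.nn` is a compact
reverse-mode autodiff library on float32 NumPy arrays with exactly the
primitives the networks need — stride-1 convolution (dilated, grouped;
im2col + BLAS matmul, chunked at 256 MB to bound peak memory), 2×2
ceil-mode max/average pooling, bilinear resampling with half-pixel
centres, batch normalization, softmax/log-softmax, dropout, deformable
bilinear sampling, and AdamW.  Every primitive's gradient is tested
against central finite differences, and convolution against a
brute-force loop oracle.  Checkpoints are single ``.npz`` archives with
the model config embedded; the loader refuses mismatched configs or
shapes.

## The phantom generator

Phantoms emulate what the method assumes about thyroid ultrasound: a
two-lobe gland silhouette (two jittered ellipses joined by an isthmus,
each with a smooth low-order Fourier boundary perturbation) brighter
than background; nodules grown inside the gland support (hypoechoic by
default, offset −0.35…−0.15) with configurable boundary irregularity —
low amplitude gives smooth benign-like shapes, high gives irregular
malignant-like ones, verified by a boundary-roughness statistic;
multiplicative gamma speckle of mean 1 whose strength parameter is the
noise standard deviation (shape = 1/σ², so larger strength means lower
SNR, verified monotonically); optional smooth vertical acoustic-shadow
bands beneath a bright arc; Gaussian blur; clipping to [0, 1].  Masks
are built first and validated against the {0, 1, 2} encoding; dataset
generation is byte-identical under a fixed seed.

What the phantoms do **not** model: wave-propagation physics, depth-
dependent attenuation/TGC, probe-specific texture, calcifications,
cystic interiors, or inter-observer annotation noise.  Passing tests on
phantoms therefore demonstrate the correctness and trainability of the
implementation, not clinical performance.

## Problem sizes used in tests

All testing runs on CPU at reduced scale, chosen as the smallest sizes
that still exercise every code path: reference-width (base 64/32) models
are verified shape-correct on a single 512×512 forward pass; gradient
coverage, determinism and comparison checks use base width 4–8 at
32–128 px; the end-to-end trainability check trains a base-width-8
DSRU-Net on eight 128×128 phantoms for 200 AdamW steps at lr 1e-3
(a deliberately overfit-friendly rate for a tiny model) and requires a
training foreground dice ≥ 0.90, a threshold fixed from pilot runs of
this configuration.  The receptive-field recurrence is cross-checked
against an empirical gradient-extent oracle on a three-level scaled
instantiation whose field fits a 64×64 canvas.

## Known limitations

* CPU-only and single-threaded BLAS-bound; full 512×512 training at
  reference width is out of scope for routine runs.
* Transposed-convolution upsampling is not offered (bilinear or nearest
  only), since all convolutions are stride-1 by design.
* The deformable layer shares one offset field across channel groups;
  per-group offsets are not implemented.
* Patient-level (grouped) validation splitting is supported only through
  the manifest; the default split is image-level.
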