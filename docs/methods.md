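# Methods

## Problem setting

A rectified stereo endoscope images the surgical site from two horizontally
displaced viewpoints. For a scene point seen at pixel (x, y) of the left
view, the same point appears at (x − d, y) in the right view; the disparity
d is inversely proportional to metric depth (Z = f·B/d for focal length f
in pixels and baseline B in mm). The package implements a multi-task
network that predicts, from a rectified pair, a dense disparity map and a
binary surgical-instrument mask, sharing one feature encoder between both
tasks so that features are computed once per view and either head can be
removed without affecting the other.

## Numerical engine

All networks run on an in-package reverse-mode automatic-differentiation
engine over NumPy float32 arrays (`stereomt.nn`). Convolutions are
evaluated by im2col + batched BLAS matrix products with explicitly written
adjoints; bilinear resizing is expressed through dense per-axis
interpolation matrices so its gradient is the transposed product; the
horizontal warp is the standard differentiable bilinear sampler with
zero-filled out-of-image reads and gradients to both the sampled image and
the disparity. SSIM window means accumulate in double precision because
the variance term E[x²] − E[x]² otherwise loses significance against the
c₂ = 0.03² stabilizer on low-variance patches. Batch normalization uses
biased batch variance during training and exponential running statistics
(momentum 0.1) at evaluation. Weights initialize Kaiming-style (fan-in,
LeakyReLU gain); batch-norm scales start at 1 and shifts at 0.

## Architecture

**Shared encoder.** Two variants produce feature pyramids at scales S2..S6
(1/2 .. 1/32 resolution): a lightweight encoder of five down-sampling
blocks of two 3×3 convolutions (stride 2 then 1, no conv bias, batch norm +
LeakyReLU 0.1) with widths 16, 32, 64, 96, 128; and a headless ResNet-34
tapped at the stem (/2) and its four stages, widths 64, 64, 128, 256, 512.
The trainable parameter counts are 469,488 (0.47 M) and 21,284,672
(21.28 M). A width-reduced `tiny` sibling (widths 8, 12, 16, 20, 24) exists
for CPU-scale experiments.

**Disparity head.** Disparity is estimated coarse-to-fine. At S6 a
unidirectional cost volume with max_disparity/32 + 1 = 11 planes (offsets
0..10) is built directly from the two feature maps; its costs are the mean
over channels of element-wise feature products (not a dot product, keeping
magnitudes mixed-precision-safe), with out-of-image source columns
contributing zero. At each finer scale the previous estimate is bilinearly
up-sampled and passed through a per-scale learned 3×3 up-scaling
convolution initialized to an exact ×2 centre tap, the right features are
warped by it, a bidirectional ±2 cost volume is built, concatenated with
the left features, and a convolutional tower (widths 128, 128, 96, 64, 32,
then a bare 1-channel regressor) adds a residual correction. At full
resolution no cost volume is built — raw-pixel matching is noisy and
skipping it tolerates ~2 px of vertical rectification error — and a 2-D
hourglass (two stride-2 stages, widths 16/32/64, fed with the up-scaled
disparity concatenated with the left image) refines the up-scaled S2 map as
a residual. All convolutions except disparity regressors carry batch norm
and LeakyReLU(0.1).

Open-design choices made here: the hourglass widths and its image input
are not externally constrained; the learned up-scaling convolution is
per-scale rather than shared; warp samples outside the image are
zero-filled; bidirectional plane order is ascending (−2..+2).

**Segmentation head.** A U-Net-style decoder ascends S6→S2: 4×4 stride-2
transposed convolutions (padding 1, so up-sampled maps exactly match the
skip sizes), skip concatenation, and two 3×3 conv + batch norm + LeakyReLU
stages whose widths mirror the encoder widths. The S2 output is up-sampled
once more and a single 3×3 convolution produces one logit channel.
Probabilities are sigmoids of logits; masks use a strict > threshold,
default 0.5, ties going to background.

## Losses

* Supervised disparity (pre-training and disparity fine-tuning): each
  scale's prediction is bilinearly up-sampled to full resolution and
  multiplied by its resolution ratio 2^(i−1), compared with ground truth by
  smooth-L1 (0.5w² below |w| = 1, |w| − 0.5 above) over valid pixels,
  ignoring ground truth above 320 px; scales are averaged. A batch with no
  valid pixels yields 0 with a warning.
* Segmentation: 0.5·WBCE + 0.5·soft-dice. WBCE weights foreground by
  β = (1 − 0.15)/0.15 ≈ 5.67 (tools cover ~15 % of frames); probabilities
  are clipped to [1e−7, 1 − 1e−7] before logs. The printed WBCE is an
  unnormalized sum; it is divided by pixel count here so the equal-weight
  mix with dice (a [0, 1] quantity) and the stated coefficients stay
  scale-balanced. Dice uses ε = 1e−5; two empty masks give loss 0.
* Self-supervised stereo (multi-task phase, S1 output only): the right
  image is warped to the left view by the predicted disparity; the loss is
  β_ss(α_ss·photometric + (1 − α_ss)·SSIM) + (1 − β_ss)·smoothness with
  α_ss = 0.9, β_ss = 0.7. Photometric is mean smooth-L1; occlusions are
  deliberately not masked. SSIM uses uniform 11×11 windows (valid
  positions only) with c₁ = 0.01², c₂ = 0.03², loss (1 − SSIM)/2. The
  edge-aware smoothness term divides disparity by the 320 px search range,
  takes forward differences, and damps by exp(−‖∂I‖) with ‖·‖ the mean
  absolute channel gradient. Uniform (not Gaussian) SSIM windows are a
  documented choice.
* Multi-task: α_mt·self-supervised + (1 − α_mt)·segmentation, α_mt = 0.2.

## Training phases

Phase 1 pre-trains encoder + disparity head under full multi-scale
supervision (segmentation layers absent). Phase 2 either continues a
single task or trains jointly (multi-task loss, disparity self-supervised
at S1 only, segmentation fully supervised). Fine-tuning phases leave the
unused head — parameters and batch-norm statistics — untouched. AdamW
(β₁ = 0.9, β₂ = 0.999, weight decay 1e−4) drives all phases; pre-training
uses a one-cycle schedule (linear warm-up, cosine anneal), fine-tuning a
constant learning rate. Augmentation applies an identical random crop and
vertical flip to every field of a sample (vertical flips keep rows aligned
and disparity values unchanged) plus per-channel color normalization. One
master seed drives initialization, data order and augmentation.

## Synthetic scenes

The generators stand in for the large rendered stereo corpora and
challenge data used at full scale; they produce scenes whose disparity is
known by construction, not by annotation.

* Textures are sums of three Gaussian-smoothed noise octaves (σ = 1.2, 4,
  12). Single-σ noise has no low-frequency energy, so the /8../32 pyramid
  scales of a 64×64 scene would see a featureless field and coarse
  matching would be impossible — an artifact absent from natural images,
  whose spectra fall off smoothly.
* Fronto-parallel scenes shift the texture by a constant disparity; the
  leftmost ⌈shift⌉ columns have no right-image correspondence and are
  invalid.
* Smooth scenes draw a base level plus Gaussian bumps (slopes kept below
  1 px/px), clipped to the requested range; the right view is synthesized
  by inverting the column map x − d(x) = u with a fixed-point iteration
  (a contraction under the slope bound), and validity combines
  in-image source columns with a forward z-buffer over right-image
  columns in which the nearest (largest) disparity wins.
* Instrument masks are unions of border-entering capsules (rectangle +
  semicircular tip) whose length/width distributions were calibrated once
  so that two tools on a 256×320 frame average ≈ 15 % coverage, the class
  balance of surgical tool datasets.

What the generators do not emulate: specular highlights, smoke, blood,
lens distortion, photometric asymmetry between views, imperfect
rectification and time-desynchronized channels. Passing the suite
therefore demonstrates the correctness of the machinery, not clinical
accuracy.

## Desk-scale experiments

CPU-scale stand-ins for the full training campaigns use the `tiny`
encoder with correspondingly reduced tower (32, 32, 24, 16, 8) and
hourglass (8, 12, 16) widths on 64×64 scenes: disparity recovery trains on
200 fronto-parallel scenes with shifts 4–28 px under full multi-scale
supervision and is scored by held-out EPE; segmentation overfits 5
generated masks to IoU > 0.95. At this scale the S6 grid is 2×2 and all
training disparities lie inside the first cost-volume plane, so the
coarsest scales contribute little and accuracy rests on the ±2 windows of
S4..S2 plus the hourglass — a known degeneracy of the reduced problem
size, not of the architecture.

That degeneracy creates an exposure-bias failure mode: as the cascade
converges on the training scenes, the residual towers only ever see tiny
prealignment errors, yet on unseen textures the degenerate coarse scales
hand them errors of many pixels that they never learned to undo. The
desk-scale configurations therefore enable `cascade_noise_px`: during
training each scale's incoming disparity estimate is perturbed by a
per-sample uniform offset (±1 px at the incoming scale) before
prealignment, while the supervised loss still targets the clean ground
truth — so every tower keeps practicing corrections across its whole ±2
window. The knob defaults to 0 (the plain scheme) and only changes the
training-time forward pass, not the objective or the architecture; with it
the held-out EPE of the recovery experiment drops roughly tenfold and its
outliers disappear.

## Ground-truth geometry

Structured-light ground truth arrives as per-pixel 3-D points in the left
camera frame. Each point is projected through both rectified 3×4 camera
matrices; the horizontal displacement of the two projections is the
disparity, written at the rounded left-view pixel. Points behind either
camera or outside the frame are dropped (counted in a report); pixel
collisions keep the largest disparity, i.e. the nearest point. Rig
constructors assert the rectification contract (row coordinates agree to
1e−9). De-interlacing replaces odd rows with the mean of their even
neighbours (idempotent by construction); black-border cropping takes the
tight bounding box of pixels with luminance > 8/255 before bilinear
resizing to the target resolution.

## Metrics

EPE is the mean absolute disparity error over valid pixels; Bad3 the
percentage of valid pixels whose error strictly exceeds 3 px; depth MAE
the mean absolute depth difference in mm after d → f·B/d conversion, with
disparities at or below 0.5 px marked invalid to cap the depth blow-up
(configurable); IoU the Jaccard index with both-empty defined as 1.0.
Frames whose valid ground truth covers at most 10 % of the image are
excluded from aggregates (strict "exceeds").

## Known limitations

* float32 everywhere; mixed precision is not implemented (full precision
  is what the correctness tests require anyway).
* The CPU engine is orders of magnitude slower than an accelerator stack;
  default problem sizes in the tests and the reproduction script are
  chosen accordingly (64×64 scenes, width-reduced models).
* ResNet-34 weights initialize randomly; loading pretrained weights is
  supported through the checkpoint mechanism but none ship with the
  package.
* The full-resolution hourglass design (widths, image input) follows this
  package's own choices where the architecture is otherwise unspecified.
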