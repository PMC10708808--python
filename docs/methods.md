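# Methods

## Problem and model

`ipseg` segments a single foreground structure (a left-ventricle-like region)
in low-resolution 2D grayscale frames, the regime typical of routine
echocardiography (112 × 112 pixels).  Two ideas drive the architecture:

1. **Inverted input pyramid.** Instead of the usual downscaling pyramid, the
   input frame is *enlarged* by bicubic interpolation to a ladder of scale
   factors (default [1, 2]; [1, 2, 4] is the full configuration).  One network
   branch is trained per rung, so the model sees progressively magnified views
   and recovers contextual detail that is scarce at native resolution.
2. **Position attention.** Organs occupy consistent relative positions across
   frames.  Each branch runs a backbone → ASPP → three PABlocks → segmentation
   head.  A PABlock pools the feature map separately over width and height,
   fuses and compresses the two directional descriptors, concatenates a
   sinusoidal positional encoding, restores each descriptor to full extent,
   replicates it across the orthogonal axis, and gates the input residually:
   `Y = X + X ⊙ σ(conv(O_h + O_w))`.

Per-scale score maps `y_s` are fused at base resolution as
`y = conv1×1(concat(y_1, …, y_S))`, with rungs above 1× bilinearly
downsampled first.

## Numerical stack

No GPU framework is used: the package ships its own reverse-mode autograd
over NumPy arrays (`ipseg.nn`), with hand-written adjoints for convolution
(tap-loop im2col + BLAS matmul), batch normalization, separable linear
resampling and adaptive average pooling.  Every adjoint is validated against
central finite differences in the test suite.  Training uses SGD with
momentum 0.9 under equal-interval step decay.

## Resampling conventions

The cubic-convolution kernel uses sharpness a = −0.5.  Free choices the
resampling literature leaves open are fixed as: half-pixel-center source
mapping `src = (dst + 0.5)/factor − 0.5`; edge replication (clamped indices)
for out-of-frame taps; output dimensions `round(factor · dim)`; 0-based
pixel-center coordinates, row-major.  Interpolated values may overshoot
[0, 1] because the kernel has negative lobes; the pyramid builder clamps at
build time while the raw resampler does not, so oracle comparisons stay
exact.  The factor-1 rung is a bit-identical copy of the source.

## PABlock parameters

* `r` (spatial compression ratio, default 64): descriptors of length `L` are
  adaptively average-pooled to `ceil(L/r)` bins with a floor of one bin, so
  non-divisible lengths (112/64) lose no positions.
* `d` (positional-encoding rows, default 512) and `base` (default 1000):
  row *i* (1-based) of the encoding holds `sin(p / base^{i/d})` for even *i*
  and `cos(p / base^{(i−1)/d})` for odd *i*.  The base of 1000 (rather than
  the more common 10000) is kept configurable.  `d` is independent of the
  channel count; the post-upscale 1-wide convolution maps `C + d → C`.
* Descriptor fusion uses a kernel-3 length-preserving 1D convolution (to mix
  adjacent positions), batch normalization over channels, and ReLU; all other
  descriptor convolutions are kernel-1.
* The residual gate is a sigmoid.  The gate convolution is initialized at
  one tenth of the usual fan-in scale so an untrained block sits near
  `Y ≈ 1.5 X` (gate ≈ 0.5) while every upstream parameter still receives
  gradient from the first step — an exactly-zero initialization would block
  gradient flow into the block's interior at step 0.

## Network assembly

* Backbones: `tiny` (three — four at output stride 16 — strided conv-BN-ReLU
  stages; a 112×112 forward pass takes well under a second on one CPU) and
  `resnet101` (standard bottleneck stack, randomly initialized).  The tiny
  backbone is the default for desk-scale work.
* ASPP follows the Deeplab-v3 recipe (parallel dilated 3×3 branches, a 1×1
  branch, optional global-pooling branch, concatenation, 1×1 projection).
  Default rates for the tiny configuration are (2, 4, 6), sized so the
  dilation span fits the 14×14 feature map of a 112×112 frame at output
  stride 8; a configuration whose span exceeds the feature extent is
  rejected.
* Scale branches hold independent parameters by default
  (`share_scale_weights` enables sharing).  The fusion convolution is
  initialized to average the scales (weight 1/S on the matching class, zero
  bias), so a single-scale model is exactly the baseline backbone+ASPP+head
  path at initialization and fusing identical maps returns the shared map.
* Loss: pixelwise two-class cross-entropy on the fused output plus auxiliary
  cross-entropy (weight 0.4) on each per-scale output against the mask
  resampled to that scale by nearest neighbor.  Fused-only supervision
  starves the outer rungs early in training.
* Step decay: "equal interval" is realized as interval = epochs/3 and factor
  0.1, both configurable.  Model selection keeps the epoch with the best
  validation mean Dice.  No data augmentation by default; a horizontal-flip
  flag exists but is off.

## Metrics

Dice, Jaccard, Precision, Recall and F-Measure are computed from exact
pixel confusion counts; F-Measure uses balance parameter a = 1, where it
coincides with Dice.  Degenerate cases: both masks empty → all scores 1;
exactly one empty → overlap scores 0, precision 1 only for an empty
prediction, recall 1 only for an empty ground truth.  Dataset scores are
means of per-image metrics (not pooled counts).  Predicted masks come from
an argmax over the two class score maps; there is no threshold knob.

## Synthetic phantoms

Each phantom is a rotated ellipse (semi-axes 13–30% of the frame, center
jitter ±8%), notched into a crescent with probability 0.4, rasterized as a
binary mask that must be a single 4-connected component covering 3–40% of
the frame (up to 100 redraws).  Rendering: foreground/background base
intensities 0.75/0.25, a random linear shading ramp of amplitude 0.15,
Gaussian blur σ = 1 px, and multiplicative Rayleigh speckle
`I · (1 + 0.35 (R − E[R]))`, clamped to [0, 1].  These values were chosen
once as a plausible desk-scale stand-in for apical-view echo frames.

What the phantoms do **not** emulate: real speckle correlation structure,
shadowing and attenuation artifacts, probe-sector geometry, anatomical
variability beyond ellipse/crescent shapes, and temporal coherence across a
cardiac cycle.  Passing the learning-sanity checks therefore demonstrates
that the pipeline trains, fuses scales and evaluates correctly — not that
the reported Dice transfers to clinical data.

Masks are rasterized at 1× only; per-scale supervision is obtained by
nearest-neighbor resampling, never re-rasterized analytically at 2×/4×.

## Desk-scale study sizes

The reference study run (test suite and `scripts/acceptance.py`) trains the
tiny backbone with factors [1, 2] on 128 phantoms, evaluates 32 held-out
frames, and uses 10 epochs at batch size 8, learning rate 0.01, momentum
0.9 — sizes chosen so the whole study runs in about a minute on one CPU
while leaving a wide margin over the all-background baseline.  The
full-scale configuration (ResNet101, factors [1, 2, 4], 150 epochs) is
expressible through the same configs but is not exercised by the tests.

## Known limitations

* Pure-NumPy training is single-threaded BLAS-bound; wall-clock scales
  roughly linearly with pixel count × channels, so the 4× rung and wide
  backbones are expensive.
* Batch normalization with very small batches (e.g. a final ragged batch of
  one) falls back to biased variance in the running-statistics update.
* Only binary (two-class) segmentation is implemented end to end; the head
  and fusion accept more classes but the metrics module is binary.
* `resnet101` is provided for architectural completeness; it is randomly
  initialized (no pretrained weights) and impractical to train in this
  NumPy stack.
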