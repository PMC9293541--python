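# Methods

## Problem setting

The task is binary semantic segmentation of white blood cells (WBCs) in
RGB blood-smear images: every pixel is labeled WBC (positive class) or
background. Red blood cells, plasma and illumination gradients belong to
the background; touching or overlapping WBCs are not separated (no
instance labels).

## Synthetic smear world

Because real annotated smear datasets are large and externally licensed,
the package ships a generator whose samples stand in for them in every
test. A scene is a seeded draw of:

- **WBCs** — rotated ellipses (semi-major axis uniform in the configured
  radius range, eccentricity uniform in [0, 0.6], rotation uniform in
  [0, π)) placed fully inside the image, each with a concentric darker
  elliptical nucleus whose radius is a uniform fraction (default
  0.45–0.7) of the cell radius. Ellipses, not circles, supply the shape
  irregularity characteristic of leukocytes.
- **RBC distractors** — fainter circles that may clip the border and never
  enter the mask.
- **Illumination** — a planar multiplicative gradient of relative
  amplitude `illumination_amplitude` (default 0.15) along a random
  direction, emulating global shade/illumination differences between
  fields of view rather than local artifacts.
- **Noise** — additive Gaussian intensity noise (σ = 3 counts by default)
  applied to the image only; the mask is the exact union of WBC ellipse
  footprints under a pixel-centre inclusion test and is independent of
  noise by construction.

Colors approximate a Romanowsky-type stain (pale pink background, purple
cytoplasm, dark violet nucleus). Defaults target 128-px images; the
reference demo scale is 300 px, and `SceneConfig.for_image_size` scales
the cell radii proportionally for other sizes (the 64-px world used in the
recovery experiment is the 128-px world at half radius). What the
generator does **not** emulate: stain batch variation, cytoplasm texture
and granularity, out-of-focus blur, cell crowding statistics of real
smears, and annotation noise. A green test on synthetic data therefore
establishes that the pipeline is implemented correctly and can learn the
stated task, not that it reaches any particular accuracy on clinical
material.

Ground-truth convention (the annotation protocol is otherwise
under-specified): the foreground is the full cell footprint — cytoplasm
plus nucleus — with a pixel counted as foreground when its centre lies
inside the ellipse.

## Preprocessing

Normalization uses one global mean and **population** standard deviation
pooled over all pixels and channels of the training images, with
stabilizer ε = 1e−10 in the denominator (`(σ + ε)`, so a constant dataset
maps to exactly zero with no numerical failure). Statistics are computed
on the training partition only, after resizing (resize-then-normalize;
the order is recorded in the serialized stats), and reused unchanged at
validation, test and inference time. A per-channel variant exists but is
off by default since the definition indexes a single global pair.

Resizing is bilinear for images and nearest-neighbour for masks (masks
stay strictly binary). Augmentation draws one rotation uniform in ±25°
and one zoom and scale factor uniform in [0.9, 1.1] per sample per epoch,
applied identically to image (bilinear, reflected borders) and mask
(nearest, zero fill, re-binarized). The named transforms are given
without ranges in the source design; the defaults above are mild values
standard for microscopy augmentation.

## Architecture

Three-level residual encoder (112/224/448 filters), each block two 3×3
convolutions with batch normalization and ReLU plus an identity shortcut
(1×1 projection + BN when channel counts differ), 2×2 max pooling after
each encoder block, and a residual bottleneck at 1/8 resolution reusing
the third-level width (the bottleneck width is unspecified in the source
design; reusing 448 keeps the parameter budget close to the stated
filter plan). Decoder levels upsample ×2 (nearest-neighbour followed by
convolution — chosen over transposed convolution to avoid checkerboard
artifacts), concatenate the same-resolution encoder features, apply
dropout 0.2 (expansive path only), and convolve at widths 224/122/122.
The 122s are implemented as printed although they are plausibly a typo
for 112; `decoder_as_printed=False` switches to 224/112/112. Same
padding everywhere so skips align without cropping. The head is a 1×1
convolution with sigmoid. `width_multiplier` scales all filter counts
with rounding to a minimum of 1 (1/16 gives 7/14/28).

The classification variant keeps the contracting path and appends
flatten → dropout → dense(n_classes, default 4) → softmax. Its published
parameter table is internally inconsistent and relies on an unspecified
"efficient netblock", so parameter totals are deliberately not
reproduction targets; this package's encoder serves as the backbone.

All layers are NumPy with hand-written backpropagation (the environment
provides no deep-learning framework): im2col/col2im convolution, batch
normalization with running statistics (counted as nontrainable
parameters), first-occurrence tie-breaking in the max-pool adjoint, and
inverted dropout. Gradient correctness is verified against central finite
differences at 1e−4 relative tolerance.

## Loss

`L = L_BCE + L_T` with unit weights (the source writes a bare sum). The
`L_T` symbol is read as the Tversky loss — the standard meaning in
segmentation — with defaults α = β = 0.5, the most conservative choice
since it reduces exactly to the soft Dice loss. Smoothing constant 1.0 in
numerator and denominator keeps the empty-mask case defined (all-zero
prediction against an empty mask gives loss 0). BCE clips probabilities
to [1e−7, 1 − 1e−7] for log stability; the analytic gradient is zeroed in
the clipped region to match the clipped forward value.

## Metrics

Confusion counts are exact integer tallies. `mean_metric` implements the
literal `TP/(TP+TN)` ratio of the source definition; since that ratio
cannot measure accuracy, the standard pixel accuracy `(TP+TN)/total` is
reported alongside and used as the headline accuracy aggregate. The Dice
coefficient uses the universal `2|A∩B|/(|A|+|B|)` (the printed union
denominator would duplicate the Jaccard definition). Conventions:
IoU = DSC = boundary F1 = 1 when both masks are empty; boundary pixels
are foreground pixels 4-adjacent to background (or the image border);
boundary F1 matches boundary pixels within a Euclidean tolerance of 2 px
at 224×224, scaled with the image diagonal for other sizes; probability
maps are binarized at 0.5. Undefined ratios (zero denominators) are
reported as NaN and excluded from aggregates. Dataset aggregates are
unweighted means over samples, formatted as percentages with two
decimals (boundary F1 stays on the 0–1 scale, as conventional).

## Training protocol

Splits: seeded shuffle, then `floor(rᵢ·n)` per partition with the
remainder to the training partition (80/10/10 default). k-fold: seeded
shuffle then round-robin (six folds default); the split and the CV
harness are independent entry points since the source uses both without
relating them. The training loop is augment (train partition only) →
resize → normalize → Adam (lr 1e−3, batch 8) on the compound loss, with
early stopping on validation IoU (patience 5) and the
best-validation-IoU weights restored at the end. The optimizer, learning
rate, batch size and epoch budget are this package's desk-scale choices;
the source states none of them. Non-finite loss aborts with a
diagnostic. Everything is deterministic given the dataset, split and
training seeds.

The recovery experiment — the stand-in for a full-scale accuracy claim —
generates 240 seeded 64×64 smears, trains the 1/16-width network on 180
with 20 for validation (the first 200 form the training pool) for 15
epochs, and requires held-out IoU ≥ 0.80 on the remaining 40; it reaches
≈ 0.99 in about two minutes on one CPU.

## Known limitations

- Pure-NumPy training is single-threaded BLAS-bound; full-width 224×224
  training is out of desk-scale reach (by design; the width multiplier
  exists for exactly this reason).
- The generator's simplified appearance model means reported metrics do
  not transfer to clinical smears.
- No learning-rate schedules, mixed precision, multi-GPU, or test-time
  augmentation.
- Instance-level metrics (per-cell average precision) and Hausdorff
  distance are out of scope.
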