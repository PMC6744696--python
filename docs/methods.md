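# Methods

## Problem and model

Nucleus detection in stained microscopy tiles is cast as dense regression:
instead of classifying pixels, the network predicts a *proximity map* whose
value at pixel (u, v) encodes closeness to the nearest annotated nucleus
center,

    y_uv = scale * (exp(alpha * (1 − D_uv / d)) − 1) / (exp(alpha) − 1)   for D_uv ≤ d,
    y_uv = 0                                                              otherwise,

with D_uv the Euclidean distance from the pixel to its nearest center.
Defaults are alpha = 3 (decay), d = 15 px (support radius) and scale = 5
(targets are multiplied by 5 to ease regression; the network output layer
is linear and regresses the scaled target directly).  The map equals
`scale` exactly at a center, falls continuously to 0 at distance d, and is
zero elsewhere, so most of every training target is background.
Distances are computed exactly (k-d tree nearest-center query from integer
pixel centers to real-valued annotation points); approximate distance
transforms are deliberately not used, since the encoding is the method's
core contract.

The regressor is a U-Net-like fully convolutional residual network:

* an input transition (one 3x3 convolution), `depth` = 4 downsampling
  residual blocks with stride-2 convolutions between them (filter count
  doubles at each halving except into the last block: base_width w gives
  channels w, 2w, 4w, 8w, 8w);
* four upsampling residual blocks connected by stride-2 transposed
  convolutions, each concatenated with its same-resolution downsampling
  counterpart;
* a multi-context aggregation path: every downsampling block's output is
  brought back to full resolution by one transposed convolution and the
  maps are summed, pooling receptive fields of several sizes so nuclei of
  different scales are represented;
* an output transition of two convolutions producing the 1-channel map.

Batch normalization follows every convolution, ELU (alpha = 1) follows
every normalization and residual addition, and dropout 0.5 follows the
convolutions of the last two downsampling residual blocks.  Blocks are
labeled 1..10 from input to output; `freeze_blocks(net, k)` excludes
blocks 1..k from gradient updates and pins their normalization statistics,
which supports the layer-transferability experiments.

Design choices where the design was genuinely open:

* **Strided transitions are 2x2, stride 2** (down) and their exact
  transposes (up).  This realizes floor-division downsampling for every
  size (75 → 37) and exact doubling upsampling (37 → 74); the upsampled map
  is zero-padded on the bottom/right to match its skip (74 → 75).  The
  3x3/padding-1 rule applies to convolutions inside residual blocks.
* **Residual block internals**: conv–BN–ELU–conv–BN plus an identity
  shortcut (1x1 conv + BN projection when channel counts change), addition,
  ELU — the standard pre-2016 residual design.
* **Multi-context combiner**: element-wise summation after projecting each
  level to `base_width` channels; summation keeps the output transition's
  input width independent of depth.  All four downsampling block outputs
  feed the path.
* **Skip pairing**: with down blocks at scales 1/2..1/16 and up blocks at
  1/8..1/1, same-resolution pairing matches up blocks 1–3 to down blocks
  3–1 and the final up block to the input transition's full-resolution map.
* **Output head**: linear.  A sigmoid head scaled by `output_scale` exists
  as a configuration used by the gradient-consistency tests, not for
  detection (a plain sigmoid cannot reach scaled targets).
* The multi-context projections are grouped with block 10 for freezing
  purposes, so "freeze the first k blocks" always means the encoder/decoder
  trunk.

No deep-learning framework is used: the package carries a small
reverse-mode automatic-differentiation engine (`micronet._autograd`) with
hand-written vector-Jacobian products for exactly the operations above,
lowered to BLAS GEMMs via im2col.  Every op is verified against central
finite differences in float64.

## Loss

Plain MSE on proximity maps admits the trivial all-zero solution because
background dominates.  The weighted MSE

    L(o, y) = 1/2 * sum_uv (y_uv + lambda * y_bar) (o_uv − y_uv)^2

up-weights nucleus interiors; y_bar is the mean of the image's gold map and
lambda = 5 by default.  The loss is normalized by the pixel count and
averaged over the batch.  Two non-obvious conventions:

* **y_bar comes from the full source image, not the crop.**  Training
  crops patches dynamically; a background-only patch of an annotated image
  keeps weight `lambda * y_bar > 0`, which is precisely what penalizes the
  collapse to zero output.  `weighted_mse` computes y_bar from the map it
  is given unless an explicit `y_bar` is passed; the training loop always
  passes the full-image value.
* **Mixed-source normalization.**  With target and auxiliary batches the
  per-iteration objective is `(gamma * sum_T l_i + sum_A l_i) / (n_T +
  n_A)`, so gamma = 1 is *exactly* the pooled batch mean, and as gamma → ∞
  the gradient direction tends to the target-only direction.  gamma
  multiplies the target loss (up-weighting scarce target data against a
  large auxiliary pool).

The analytic last-layer gradient under a sigmoid head,
`(y + lambda*y_bar)(o − y) o (1 − o)` per pixel, is kept as an independent
oracle against the autodiff route; the tests require agreement to 1e-6
absolute and to 1e-5 relative against finite differences.

## Training

SGD with Nesterov momentum 0.9, weight decay 1e-6, initial learning rate
0.01, batch size 4.  Four 200x200 patches per image are cropped freshly
each iteration (full-scale profile), normalized per channel to zero mean
and unit variance, and augmented by a geometric transform applied
identically to image and label: a dihedral-group element (right-angle
rotations and mirroring — exact on sparse label maps; arbitrary-angle
rotation is available behind a flag but interpolates), a shift of up to 8
px with reflect padding, and an elastic distortion from a smoothed random
displacement field (grid spacing 32 px, peak magnitude 8 px, smoothing
sigma 4 px — mild enough to keep nuclei intact; unit-order interpolation).
The learning rate divides by 10 whenever pooled validation F1 (at the best
xi on a small grid) has not improved for `patience_iterations`, and the
decay stops below 1e-4.  Validation runs every `val_interval` iterations
(1000 in the full profile); momentum is not reset on decay.  Snapshots are
taken every 2000 iterations; if the loss turns NaN the last snapshot is
restored and training aborts.

All randomness — corpus generation, initialization, patch draws,
augmentation, dropout — flows from explicit seeds, and runs are
bit-reproducible on a fixed BLAS configuration.

### Problem sizes

Two named profiles exist.  The *full* profile mirrors a realistic
deployment (500x500 tiles, base_width 32, 1e5 iterations).  The *desk*
profile — base_width 8, 64x64 tiles, identity crop with one patch per
image draw, 600 iterations, validation every 150 — is the package's own
test-scale condition: the synthetic task is easy enough that the desk
network converges well within that budget, and the whole end-to-end study
(150 train / 30 validation / 30 test tiles) runs on one CPU in minutes.
The lambda-ablation study uses an even smaller paired setup (48x48 tiles,
24/6/10 split, 150 iterations, identical corpora across the compared
settings) because the lambda = 0 collapse shows up almost immediately.

## Detection and evaluation

Prediction is a single full-image forward pass (the network is fully
convolutional), with the same per-channel normalization as training.
Pixels below `xi * max(map)` are suppressed and local maxima of the result
are the detected centers.  A local maximum is a pixel ≥ all neighbors
within Euclidean distance `min_distance` (default 6 px, about the smallest
plausible nucleus radius under d = 15); connected equal-valued plateaus
collapse to their centroid, and border pixels are eligible.  Because the
threshold is relative to the map maximum, detection is invariant to
positive rescaling, and raising xi can only remove detections.

Scoring: each annotation owns a gold disk of radius 16 px.  Detections are
assigned to annotations by minimum-total-Euclidean-distance one-to-one
(Hungarian) assignment; pairs beyond the radius carry a sentinel cost
larger than any feasible total, and sentinel pairs are dissolved into an
FP + FN after solving.  Precision, recall, F1 (harmonic mean) and the mean
Euclidean distance over true positives summarize a report; multi-image
results pool counts (micro-averaging; per-image averaging is available),
and dataset-level aggregation reports mean ± sample standard deviation.
Degenerate conventions: no detections with annotations present gives
P = R = F1 = 0; an empty scene with no detections gives P = R = F1 = 1.
The operating xi maximizes validation F1 over a grid; ties break toward
the larger (more conservative) xi.

## The synthetic corpus

Real nucleus-detection corpora are institution-held H&E crops, so the
package generates its own study material: elliptical hematoxylin-dark
nuclei (anti-aliased edges, radial intensity falloff, random orientation
and eccentricity, per-nucleus color jitter) over an eosin-pink background
with low-frequency texture, per-pixel Gaussian noise, and — importantly —
non-annotated distractor blobs (eosin-dark stromal/cytoplasmic clutter,
default 8–14 per tile at 90% opacity).  The distractors overlap the
luminance range a naive blob detector would threshold on, so high F1
requires the network to discriminate hematoxylin hue and shape rather than
darkness alone; without them an untrained network's map already localizes
many nuclei.  Dart-throwing
placement keeps non-overlapping nuclei at pairwise distance ≥ r_i + r_j; a
configurable fraction of nuclei is instead placed touching an existing one
(center perturbed to 0.85 of the radius sum).  Styles bundle the palette,
density and size distribution; the three defaults differ enough that a
channel-mean classifier separates them, which is what makes cross-style
(target vs auxiliary organ) experiments meaningful.  Default geometry for
64x64 tiles: 8–14 nuclei of radius 4–7 px, 10% touching.

What the generator does *not* emulate: chromatin texture, cytoplasm and
stromal structure, stain co-localization, slide-level illumination
gradients, imaging artifacts, and the annotation noise of human markers.
Passing the end-to-end tests therefore demonstrates that the pipeline —
encoding, optimization, detection, matching — is implemented correctly and
can recover known geometry from images with clutter, touching objects and
scale variation; it does not certify accuracy figures on real tissue.

## Numerical notes

* Normalization guards: a constant channel normalizes to zero (epsilon in
  the divisor); batch-norm epsilon 1e-5; running statistics use momentum
  0.1 with the unbiased variance.
* He-normal weight initialization, zero biases, per-network seed.
* The network accepts any input ≥ 2^depth on a side (16 px at depth 4);
  `predict` reflect-pads smaller images down to an absolute floor of 8 px
  and crops the output back.
* Matching cost sentinel: `(n_det + n_ann + 1) * (radius + 1)`, strictly
  larger than any feasible total assignment cost.
* Checkpoints are versioned NumPy archives holding weights, normalization
  statistics, the architecture spec, the encoding parameters and the
  training seed; loading verifies the version and (optionally) an expected
  spec.

## Known limitations

* CPU-only; a full-profile run at 1e5 iterations is impractical without a
  GPU framework and is exercised only through its configuration object.
* The desk-scale F1 reflects the synthetic task's difficulty, not clinical
  performance.
* Hungarian matching is O(n^3) per image — fine for hundreds of nuclei,
  slow for whole slides (out of scope).
* Elastic augmentation interpolates label maps linearly, which slightly
  flattens proximity peaks; right-angle rotations and mirroring are exact.
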