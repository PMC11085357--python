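# Methods

## The problem

Image-based phenotyping of *Arabidopsis thaliana* asks two questions of
every top-view rosette photograph: *which accession (genotype) is this
plant?* and *how far along is it in its growth?*  `phenonet` answers both
with a single multi-task convolutional network — a shared feature trunk
feeding a softmax classification head and a ReLU regression head — and
ships everything around it: LAB-colour-space plant segmentation, the
evaluation metric suite, Grad-CAM inspection, an experiment harness, and a
synthetic image generator with ground-truth masks so the full pipeline is
testable without any external data.  A single-task variant of the same
trunk classifies fluorescence-style organelle images (chloroplast /
mitochondria / peroxisome).

## Network

Input is a square RGB image (reference size 150 × 150, configurable),
scaled into [0, 1] by dividing by 255.  The trunk is

    Conv(16, 5×5) – BN – ReLU
    Conv(32, 3×3) – BN – ReLU – Conv(32, 3×3) – BN      (main branch)
    Conv(32, 1×1) – BN – ReLU                            (skip branch)
    addition – ReLU

followed by global pooling and a shared FC(64)–ReLU layer.  Head A is
FC(K) + softmax over the K classes; head B is FC(16)–ReLU–FC(1)–ReLU,
producing a non-negative scalar day.  All convolutions are stride-1 with
"same" zero padding; weights are He-normal, seeded.

Design choices in the open parts of this architecture:

* **Pooling** is the concatenation of global *average* and global *max*
  pooling (64 features).  A plain average dilutes the activation of a
  seedling that occupies a few dozen pixels of the frame into near-zero
  channel means; the max half preserves those peaks.  Empirically this is
  the difference between the classifier plateauing and converging on
  small-plant images.  Plain average pooling remains available
  (`NetworkSpec(pooling="avg")`).
* **Joint loss**: `L = CE(class) + λ · MSE(day / day_scale)` with λ = 1 and
  `day_scale = 22` (the observation window in days), so both terms are
  O(1).  λ is configurable; λ = 0 reduces exactly to cross-entropy.
* **Optimiser**: Adam at the stated learning rate 0.001.  "Iterations"
  are mini-batch updates; the batch is `min(batch_size, n_train)`.
* **Regression-head initialisation**: the output layer starts with
  down-scaled weights (×0.05) and bias 0.5 (the middle of the normalised
  day range).  With a plain He-scaled initialisation the head starts far
  above the targets, the first updates slam the pre-activation below zero
  for every input, and the output ReLU dies irreversibly — a failure we
  observed, not a hypothetical.

The engine itself (`phenonet.nn`) is a compact numpy implementation —
im2col-free convolutions as sums of shifted matrix products, batch norm,
manual backprop, Adam — with every layer checked against finite-difference
gradients in the test suite.

## Segmentation

Vegetation is separated from soil in CIE L*a*b*: leaves are strongly green
(a* ≪ 0), soil is red-brown (a* > 0), and lightness lives entirely in L*,
so thresholding a* is invariant to uniform brightness changes.  The
threshold defaults to Otsu's method on the a* channel (a fixed threshold
is available), with the mask taken as `a* ≤ t` to match the skimage
convention for dark-side objects.  Because Otsu always produces a split,
an image with no vegetation would otherwise yield a spurious mask; the
mask is rejected if its mean a* is above −5 (not actually green).
Components under `min_region_px` (default 25) are removed and a gentle
opening (disk radius 1) cleans speckle.  Masked images are the original
multiplied per-channel by the binary mask; network inputs are resized
bilinearly with anti-aliasing (masks nearest-neighbour).

On the synthetic suite (100 rosettes, mixed accessions and days, 320 px)
the mean IoU against generator ground truth exceeds 0.99; the acceptance
threshold is 0.90.

## Metrics

Classification metrics are one-vs-rest from a K×K confusion matrix (rows
actual, columns predicted): accuracy (TP+TN)/n, sensitivity TP/(TP+FN),
`specificity_eq3` TP/(TP+FP), FPR FP/(FP+TN), and F1 as the harmonic mean
of sensitivity and precision.  `specificity_eq3` is algebraically a
*precision*; it keeps this name because the evaluation protocol this
package mirrors defines specificity with exactly that formula.  It is
aliased `precision`, and the conventional TN/(TN+FP) is exposed as
`specificity_standard`.  Headline numbers are unweighted macro averages
plus overall accuracy = trace/n.  Zero denominators return 0.0 with a
warning rather than NaN, keeping downstream reports deterministic.

Regression: RMSE; R² about the mean of the true days; and RPD, the
*population* standard deviation (1/n, not 1/(n−1)) of the true days
divided by RMSE.  One published caption reads RPD's numerator as the SD of
*predicted* days; the standard chemometric definition (SD of reference
values) is used here.  Per-day residual groups (ŷ − y keyed by true day)
back the day-wise boxplots.  All formulas are verified against a
brute-force count-and-plug oracle on 1,000 random instances to 1e-12.

## Grad-CAM

For a chosen output (class logit or the regression head), the gradient
with respect to the trunk activation (the ReLU after the residual
addition — the deepest spatial layer) is spatially averaged into
per-channel weights; the weighted channel sum is ReLU-rectified, bilinearly
upsampled to the input size and min-max normalised.  All-zero maps skip
normalisation.  The focus score of a heatmap against a plant mask is
mean(inside) − mean(outside); positive values mean the model attends to
the plant.

The focus experiment explains the *day-regression* head, whose evidence
(plant area) is unambiguously localised on the plant; on converged desk
models its heatmaps are plant-focused on essentially every image.
Class-head attributions are also available and are usually plant-focused,
but can legitimately be diffuse for a class the model recognises partly
by the *absence* of the other classes' hues — with four accessions
separated mainly by leaf colour, the logit of the most soil-like hue
draws some of its evidence from channels that are active off-plant.

## Synthetic data

The generator emulates the structure of the real study material, not its
photometry.

**Rosette series.**  Each accession has a leaf-emergence rate (leaves/day),
leaf-elongation rate (px/day at the 320 px reference scale), leaf aspect
ratio and hue; the four defaults differ pairwise in several fields.  A
plant is a sequence of elliptical leaves placed at golden-angle increments
around a jittered centre; leaf *i* unfolds at a visible start length
(24 px at reference scale — real day-1 frames show an established
seedling, not an invisible one) and elongates linearly.  Every leaf is
anchored with a vertex at the rosette centre and all its dimensions scale
together, so the rasterised plant mask at day *d* is exactly a subset of
the mask at day *d*+1 (monotone growth, tested as an invariant).  Leaves
get multiplicative per-pixel texture (σ = 8%): real leaves are not flat in
colour, and a flat histogram is degenerate input for Otsu thresholding.
The soil background darkens linearly with the day (default 1.8 intensity
units/day) under static per-plant noise — background pixels therefore
carry weak day information, which is what makes the
background-vs-no-background comparison meaningful on synthetic data.

Randomness: one root seed; per-plant child streams
(`SeedSequence(seed, spawn_key=(accession, plant))`), so adding plants
never reshuffles existing ones, and a plant's traits are drawn before any
day-dependent rendering, so the same stream rendered at different days
shows the same individual growing.

**Organelle images.**  Dark-field frames of bright pseudo-stained
elliptical blobs whose shape statistics alone encode the class: few large
round blobs (chloroplast), many small elongated ones (mitochondria),
intermediate round dots (peroxisome).  Blob semi-axes are
(r·√e, r/√e) so area is πr² regardless of elongation e and the
equivalent radius measured from the image estimates r directly (tested to
within 15%).  Reference parameters are given at 1024 px; the desk preset
defines its own parameters at 48 px rather than scaling proportionally,
which would make mitochondrial blobs sub-pixel and erase the class signal.

**What the generator does not emulate** — and hence what passing tests do
*not* establish about real data: photorealistic leaf shape and occlusion
order, specular soil texture, illumination drift, colour-calibration
error, confocal optics and fluorophore spectra, insect damage or moisture
effects.  Recovery results on synthetic data demonstrate that the
pipeline is correct and the signal the model is designed to use is
recoverable; they say nothing about accuracy on the real image set.

## Experiments and problem sizes

The desk preset — 4 accessions × 5 plants × 22 days at 96 × 96, network
input 48 × 48, batch 16, 500 iterations (650 for the organelle task, both
at learning rate 0.001) — is the configuration all recovery tests and the
acceptance script use; it trains in roughly two minutes per run on one
CPU core.  The full-scale layout (97 plants at 320 px; 300 images per
organelle class at 1024 px) is available as presets for users with more
patience.

* **Background experiment**: two arms with identical seeds — raw images
  vs segmentation-masked images — reporting paired classification and
  regression metrics and their deltas.
* **Interval experiment**: thinning each series to every (k+1)-th day
  starting at day 1 ("k skipped days"), k = 1..5.  This convention is
  chosen because at k = 4 it retains exactly five days per plant
  ({1, 6, 11, 16, 21}), matching the published description of that task;
  k = 0 is the identity.  Training-set size strictly decreases with k;
  wall-clock time is recorded but never asserted (hardware-dependent).
* **Organelle experiment**: the single-task classifier on three synthetic
  classes, trained at the frames' native resolution.

Reports serialise to JSON with a schema version; every arm records its
seed and config snapshot.  The full pipeline under one root seed is
bit-reproducible on one machine (weight init, split, batch order and
generator output are all seeded).

## Known limitations

* The numpy engine is CPU-only and unoptimised beyond BLAS matmuls;
  full-scale (150 × 150, 2134-image) training is possible but slow.
* Training-mode batch statistics make the loss curve noisy at batch 16;
  validation metrics use running statistics.
* Otsu-on-a* assumes a red/green contrast between background and plant;
  it would need the fixed-threshold mode for, e.g., green backgrounds.
* The synthetic organelle classes are deliberately cartoon-simple; they
  exercise the single-task pipeline, not microscopy realism.
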