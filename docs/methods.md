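# Methods

This note documents the models, the synthetic data they are validated on,
the numerical choices, and the known limitations of the package.

## Problem setting

A washed soybean root is photographed flat on a uniform blue tray. The
quantities of interest are (i) the total number of nodules on the root,
(ii) the distribution of nodule sizes, and (iii) where nodules sit along
the taproot. The pipeline estimates these from a single RGB image by
combining an object detector (nodules), a semantic segmenter (taproot),
and deterministic geometry (dilation, skeletonization, projection).

## Nodule detector

Dense single-class detection: anchors of several scales and aspect ratios
are tiled over the feature map(s) of a convolutional backbone, and two
weight-shared subnetworks predict, per anchor, a sigmoid nodule confidence
and four box offsets `(dx/aw, dy/ah, log(gw/aw), log(gh/ah))`.

* **Losses.** Classification uses the focal loss
  `FL(p_t) = −α_t (1−p_t)^γ log p_t` with `α = 0.25`, `γ = 2`;
  `α_t = α` for foreground anchors and `1−α` for background (the
  convention of the loss's original formulation — the weight tracks the
  rare class). The focal term suppresses the loss of the abundant,
  easily-classified background anchors so the sparse nodule anchors
  dominate the gradient. Box regression uses the standard smooth-L1 with
  transition point `t = 1/9`: `0.5 x²/t` for `|x| ≤ t`, else `|x| − t/2`
  (the once-differentiable form; a piecewise definition without the 0.5
  factors would be discontinuous at the transition).
* **Initialization.** Subnetwork convolutions: Gaussian weights
  (σ = 0.001), zero biases. The final classification bias is
  `−log((1−π)/π)` with `π = 0.01`, so every anchor starts with foreground
  probability ≈ 0.01; without this the all-background loss of a dense
  detector is enormous at step 0.
* **Anchor assignment.** IoU ≥ 0.5 → positive, < 0.4 → negative,
  in-between ignored; the best-overlapping anchor of every ground-truth
  box is force-matched so small objects are never unassigned. The
  classification loss is summed over anchors and normalized by the number
  of positives.
* **Architectures.** `full`: a 50-layer bottleneck-residual backbone with
  a 256-channel feature pyramid (strides 8–128) and 4×256-filter heads.
  `tiny`: a three-stage backbone (8/16/32 channels) with a single stride-8
  level and 2×32-filter heads, small enough to train on one CPU in
  minutes; head and anchor semantics are identical. Both are built on the
  package's own numpy layer library (`snap.nn`: im2col convolution,
  batch-norm, 2×2 max-pool, 2×2 transposed convolution, dropout, Adam),
  whose gradients are finite-difference-tested in the suite.
* **Training.** Adam, initial learning rate 1e-3. An 80/20 image split is
  made *before* augmentation; augmentation is horizontal/vertical flips
  (probability 0.5 each), rotation/shear up to 0.1 rad, scale/translation
  up to 10%. Iterations count optimizer steps.
* **Inference.** The image is padded on the right/bottom with edge
  replication to multiples of 256, processed in disjoint 256 × 256 tiles,
  tile detections are mapped back to image coordinates, merged, and
  de-duplicated with global NMS (IoU 0.5); finally clipped to the original
  bounds. Padding content and cross-tile duplicate handling are design
  choices of this package.

## Anchor configuration strategies

* **default** — scales `{2^0, 2^(1/3), 2^(2/3)}`, ratios `{1:2, 1:1, 2:1}`
  on the standard five-level pyramid. Suitable for objects ≥ 32 px.
* **percentile** — box size is defined as `sqrt(area)` (aspect-invariant);
  a normal distribution is fitted (method of moments) to sizes and to
  *log* aspect ratios (so 1:2 and 2:1 are symmetric), and the k
  equidistant percentiles `p_i = i/(k+1)` of each fit become the anchor
  set; each percentile size is divided by the nearest pyramid level's base
  size to yield a scale multiplier.
* **de** — differential evolution (rand/1/bin, population 20, F = 0.8,
  CR = 0.7, no polishing for determinism) maximizes the mean over
  annotated boxes of the best centered IoU against any anchor shape. The
  default configuration is seeded into the initial population, so the
  optimized result never scores below the default.

## Taproot segmenter

Three encoder blocks (two 3×3 conv + batch-norm + ReLU, then dropout),
2×2 max-pool between levels, a bridge block, and three decoder blocks
(2×2 transposed-conv upsampling, skip concatenation, two conv+BN+ReLU,
no dropout), closing with a 1×1 convolution and sigmoid. Channels double
per level: 64/128/256 with a 512 bridge in the full variant. Counting
every parameter — including the four batch-norm entries per channel
(scale, offset, moving mean, moving variance) — the full variant has
exactly **7,708,609** parameters; this is the unique layout among the
candidates we enumerated that reproduces that checksum, and a constant-
width variant (`narrow=true`) is kept as a configuration option.
A closed-form counting oracle (conv `k²·c_in·c_out + c_out`, BN `4c`,
transposed conv `4·c_in·c_out + c_out`) is asserted against the built
network for several widths and depths.

Training: Glorot-uniform weights, zero biases, Adam (batch 4, lr 1e-3),
soft Jaccard loss `1 − (Σ GD + ε)/(Σ G + Σ D − Σ GD + ε)` with ε = 1 for
empty-mask stability; flips, zoom to 120%, 5% translation, rotation up to
15°; 80/20 split before augmentation. Inference thresholds the probability
map at 0.5 and (by default) keeps the largest connected component, since
the taproot is a single structure. Inputs not divisible by 2³ are padded
symmetrically and the output cropped back.

## Representative-image selection

Images are reduced to features by bilinear downsampling, a shallow
convolutional autoencoder (one stride-2 2×2 conv encode layer, mirrored
transposed-conv decode, MSE reconstruction), flattening, and PCA (either a
fixed component count or a variance target; components are sign-fixed so
the largest-magnitude loading is positive, making runs reproducible). The
subset R maximizes the uncapacitated facility-location function
`f(R) = Σ_w max_{r∈R} (d_max − d(w, r))` with Euclidean d and `d_max` the
maximum pairwise distance over the whole set, computed once — this makes
similarities non-negative and f monotone submodular, the regime in which
greedy forward selection (ties to the lowest index; `f(∅) = 0`) is
guaranteed to reach at least `1 − 1/e` of the optimum. The suite verifies
the guarantee against exhaustive optima on 8-point instances.

## Spatial quantification

The taproot mask is dilated by a disk (radius configurable; default 10 px
at the 1024-wide reference canvas, ≈ 2× the median nodule radius, with a
scale-with-width option). A detection is a taproot-zone nodule iff the
pixel containing its box center is foreground in the dilated mask. The
mask is thinned to a one-pixel skeleton; the longest endpoint-to-endpoint
(Dijkstra) path on the 8-connected skeleton graph is taken as the taproot
spine, ordered from the endpoint with the smallest y (top of the image as
soil-line proxy; closed-loop skeletons fall back to the topmost pixel,
logged). Arc length accumulates 1 for axial and √2 for diagonal steps.
Each detection is projected to the nearest skeleton point (ties to the
smaller arc position); positions are reported in pixels from the top and
normalized by the spine length, histogrammed in 10 equal bins.

Two measured properties of this definition are worth knowing:

* Thinning a straight bar of width W trims about W/2 from each end and
  wiggles within a pixel near the ends, so the spine length of an L×W bar
  is ≈ L − W, and arc positions carry ~2 px of end slack.
* Nodules attached to lateral roots near the branch junction necessarily
  sit inside *any* dilated taproot zone. On synthetic scenes the zone
  count captures 100% of truly taproot-attached nodules but overcounts by
  ~10–25% depending on the dilation radius. This is a property of the
  center-in-dilated-mask definition itself, and is consistent with
  taproot-zone counting being the weakest quantity in this family of
  pipelines.

## Synthetic scenes

A scene is a uniform tray background (with a random-direction linear
illumination gradient and additive Gaussian noise), one taproot —
a sinusoidally deviating centerline with a linearly tapering width
profile, rasterized row-wise so the stored mask is exactly the centerline
with its width profile — lateral roots (thinner, bending downward),
nodules, and optional cyst-like distractors (smaller, paler, lemon-shaped,
rendered but never listed in the ground-truth boxes, emulating the
cyst/nodule discrimination problem). Nodule counts are negative-binomial
(overdispersed across plants, mean 40, dispersion 2 at the reference
canvas). Radii are log-normal with median 5 px at the 1024-wide
reference — a 50 cm tray imaged at 1024 px gives ~0.5 mm/px, so typical
2–5 mm nodules span 2–6 px in radius — and log-sd 0.3. A configurable
fraction attaches to the taproot; the attachment class is drawn once per
nodule, before any placement retry, so the on-taproot count is exactly
binomial. Centers offset from the root centerline by roughly the local
half-width plus a fraction of the nodule radius (nodules bulge from the
root flank). Placement is rejection-sampled against center overlaps and
image borders; an unplaceable nodule raises a generation error naming the
culprit parameter, and the batch generators retry such a scene a bounded
number of times with a re-derived seed (logged — this truncates only the
physically unpackable extreme of the count distribution). Ground truth
boxes are the tight bounding boxes of the rendered elliptical blobs.
Length-valued defaults scale proportionally with canvas width.

What the generator does *not* emulate: soil debris, specular water
reflections, root occlusion/clumping, texture similarity between roots
and nodules, and blur. Passing the end-to-end study therefore shows the
pipeline machinery is correct and trainable, not that the tiny models
would reach the same accuracy on field photographs. Boundary rejection
slightly thins the large-radius tail (measured ≈ −4% on the median),
well inside the 10% recovery tolerance asserted in the suite.

## Evaluation

Predictions are consumed in descending confidence; each matches the
unmatched truth with the highest IoU ≥ threshold (default 0.5, stated in
every report). A second hit on an already-matched truth is a false
positive ("twice-counted" nodule); unmatched truths are false negatives.
Sensitivity = TP/(TP+FN), precision = TP/(TP+FP); zero denominators yield
NaN sentinels, not exceptions. AP integrates the precision envelope over
recall (all-point interpolation — the direct discretization of
`∫ p(r) dr`), with score ties broken by box x for run stability; the
suite checks exact agreement with an independently coded brute-force
reference on random instances. Count agreement uses the ordinary
coefficient of determination `1 − SS_res/SS_tot`. Pooled-image AP places
each image in its own coordinate band so cross-image overlaps are
impossible; per-image values are reported alongside.

## Scaled end-to-end study

`snap.experiments.run_scaled_study` is the desk-scale analogue of a field
validation: 100 scenes at 192 × 256 px (nodule radius median 6 px,
negative-binomial counts with mean 10 and dispersion 4, four laterals, one
distractor), 80 train / 20 held out. Percentile anchors (3 scales ×
3 ratios, single stride-8 level, base 16) are fitted to training boxes;
the tiny detector trains for 800 Adam steps (batch 4) and the tiny
segmenter (base width 8) for 120 steps (batch 4). The detector score
threshold is selected **on training scenes only** (best balanced operating
point: max of min(sensitivity, precision), F1 tie-break), then
sensitivity, precision, pooled AP and per-scene count R² are measured on
the 20 held-out scenes. Problem sizes were chosen so the whole study runs
in minutes on one CPU while leaving the workflow identical to the
full-resolution pipeline.

One training-recipe detail matters at this scale: with the full model's
subnet initialization (Gaussian σ = 0.001) the two-layer tiny heads start
almost dead — activations pass through two near-zero convolutions — and
the onset of learning within a few hundred Adam steps becomes a
symmetry-breaking lottery across seeds. The study therefore initializes
the tiny heads with σ = 0.01 (the customary value in this detector
family), which makes convergence onset reliable; the full variant keeps
σ = 0.001. Both are exposed in `DetectorTrainConfig.subnet_init_sigma`.

## Known limitations

* Training on the numpy backend is single-threaded and meant for the tiny
  variants; the full detector/segmenter build and run forward passes but
  are impractical to train here.
* Training reproducibility is at the level of seeded initialization and
  data order; bitwise equality across BLAS builds is not promised (the
  run manifests declare this).
* Lateral-root nodule positions, multi-class labels, and COCO-style
  averaged-IoU AP are out of scope.
* The detector's parameter count is reported but not asserted against any
  external figure; published parameter totals for detector frameworks
  depend on head/backbone accounting conventions that are rarely stated.
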