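# Methods

## Problem and scope

The package grades single-embryo, single-channel 8-bit micrographs of
bovine blastocysts (initial to expanded stage) on the IETS 3-point scale
and evaluates the grading against a consensus template: the mode of three
examiner labels, with the all-distinct tie (1, 2, 3) resolved to the median
grade 2 — on an ordinal scale the median is the least surprising consensus.
Multi-embryo frames, cleavage-stage morphology, colour information and
time-lapse kinetics are out of scope.

A fixed convention holds throughout: pixel coordinates are (row, col),
0-based, origin top-left; circles store cx = column, cy = row; angles are
degrees clockwise from 12 o'clock.

## Synthetic data

No public corpus with examiner panels exists, so the generator in
`synthgen` is first-class, tested code and defines the study conditions.
It renders, per image: a jittered-circle embryo (radius 70–95 px in a
256 px frame), a bright zona pellucida ring (intensity 205, outer 12% of
the radius), a trophectoderm band (150) completing the outer quarter, a
dark blastocoel (95), and a compact bright ICM blob (190, radius 0.22 r,
centred at 0.45 r) at a uniformly random polar angle — random so the
rotation stage is genuinely exercised. The scene is blurred (σ = 1.5 px)
and degraded by four grade-scaled knobs:

| knob | grade 1 | grade 2 | grade 3 | unit |
|---|---|---|---|---|
| speckle sd (inside embryo) | 3 | 8 | 15 | intensity |
| boundary jitter (low-order harmonics) | 0.012 | 0.035 | 0.07 | fraction of r |
| debris blobs outside embryo | 0 | 3 | 7 | count |
| ICM fragmentation | 0 | 0.35 | 0.7 | 0–1 |

Fragmentation renders as intensity mottling *inside* the ICM footprint
(dark pits carved by a short-correlation random field) rather than removal
of pixels: the texture breaks up — which is what the GLCM features measure
— while the blob's centre of mass stays put, keeping the pose ground truth
meaningful. The knob defaults were fixed once so that the classes overlap
mildly: separable, but not trivially so. The strict monotonicity of
speckle, jitter and debris across grades is enforced as a config invariant.

Examiners: each of three reports the true grade with probability
1 − confusion (default 0.1), otherwise an adjacent grade; grade 2 splits
its confusion mass equally between 1 and 3. At confusion 0.1 the consensus
matches the true grade for ≈97% of images, so the consensus template the
classifier chases is itself mildly noisy — as in practice.

What the generator does *not* emulate: optical blur anisotropy, uneven
illumination fields, partial embryos at the frame edge, stage debris
touching the zona, and real biological texture. Passing tests therefore
demonstrate that the pipeline recovers the constructs the generator
encodes, not clinical performance.

## Preprocessing

Brightness is standardised by an affine remap taking the within-circle
mean/sd to 128/30 (global statistics when no circle is known), clipped to
[0, 255]; a constant image is a degenerate-input error. The remap is exact
before clipping and idempotent to within quantisation.

The ICM detector thresholds (Otsu) the smoothed (σ = 2.5, suppressing
zero-mean speckle) inner compartment — the disk of radius 0.78 r, where the
ICM sits anatomically — closes small holes, discards components under
25 px, and scores each remaining component by
area × mean intensity × compactness (4πA/P², capped at 1); the compactness
factor rejects ring slivers. The returned angle is the component's
centroid weighted by squared brightness excess over the threshold, which
keeps dim speckle tails attached to the component from dragging the
estimate. If no component clears a 10-intensity-unit contrast margin the
image has no detectable ICM; the pipeline then skips rotation (angle 0),
which degrades gracefully because the texture features are angle-averaged.
Detect → rotate → re-detect lands within 5° of 12 o'clock on generator
fixtures of every grade.

## Segmentation

Hough detection runs on a Sobel-magnitude edge map thresholded at Otsu
level, scanning radii in [0.2, 0.45] × frame size at step 2 with a unit-step
refinement around the coarse winner. The accumulator is normalised by
circumference, so the reported peak is the supported fraction of the
circle; peaks under 0.25 raise a no-embryo error. Median centre/radius
error on generator fixtures is under 1 px (grade-3 boundaries, jittered by
up to 7% of r, can be off by a few more).

The ring/inner split is geometric: the annulus between r(1 − f) and r with
f = 0.25, matching the generator's zona + trophectoderm span. Shape
features use not this idealised disk but the actual thresholded,
hole-filled silhouette, which retains the boundary-irregularity signal.

Watershed treats *intensity* as altitude and floods from the regional
minima that survive h-minima suppression (default depth h = 10 intensity
units) — marker control keeps noise pits from fragmenting the labelling,
and deepening h can only merge basins, never split them. A flat surface
yields a single region by convention.

## Features (36) and reduction (24)

The registry (`features.FEATURE_REGISTRY`) is declared data and the single
source of truth for name order and provenance: 3 circularity + 12 regional
intensity statistics + 2 area fractions + 14 GLCM/Haralick + 4 watershed +
1 normalised radius. GLCMs are computed on mask pixels only (out-of-mask
pixels get a sentinel level whose row/column is discarded before
normalisation), quantised to 32 levels over the mask's own intensity range,
symmetrised, and averaged over four directions; entropy uses the natural
log with 0·log 0 = 0, and the correlation of a zero-variance matrix is
defined as 0. The isoperimetric ratio uses a subsampled iso-contour
perimeter (every 5th vertex), which is accurate for both smooth and
polygonal silhouettes where raw pixel-boundary counting overestimates a
circle's perimeter by ~6%.

Reduction is greedy Pearson pruning: repeatedly take the retained pair
with the largest |r| above the threshold (0.9) and drop its member with the
larger mean |r| to everything else (ties resolve by registry order). The
reference configuration also fixes the output at 24 variables — the
network's input width. The target acts as a floor *and* a target: the
threshold loop stops once 24 remain, and if more survive it, the same
mean-|r| ranking continues down to 24. Purely data-driven pruning
(`target_dim=None`) is available and is the only mode that guarantees no
retained pair exceeds the threshold. The reduction is fitted on training
rows only and applied to the other splits by feature name.

## Classifier and evolutionary search

The network is a 1–2 hidden-layer perceptron (layer widths 2–64; logistic,
tanh or ReLU), softmax over the three grades, trained by mini-batch
(batch 16) gradient descent with momentum on cross-entropy; inputs are
z-scored with training-split statistics stored in the model. Weight
initialisation and batch order derive from the genome's seed, so training
is bit-exact reproducible; `epochs=0` returns the untouched initialisation
with an empty loss curve. Prediction is the softmax argmax with ties broken
toward the lower (better) grade.

The genetic algorithm searches genome space — topology and training
hyperparameters, with backpropagation supplying the weights — because
fitness evaluations stay cheap and the search space stays small; evolving
raw weights directly was the rejected alternative. Defaults: 2 islands ×
10 genomes × 20 generations, tournament k = 3, uniform crossover p = 0.5,
per-gene mutation p = 0.1 (re-draw within range; learning rate is
log-uniform on [10⁻³, 0.3]), per-island elitism, and every 5 generations
the best genome of each island replaces the worst of the next island on a
ring. Fitness is exact validation accuracy, cached per genome tuple. The
best-ever fitness is non-decreasing by construction; the winning genome is
retrained on the training split before blind evaluation.

Splits are 70/15/15 by largest-remainder rounding (126 → 88/19/19),
stratified by consensus label while preserving the exact global sizes; a
class that cannot appear in every split raises a stratification error.

One master seed fans out to synthesis, splitting, the GA and weight
initialisation through named substreams (`gann.derive_seed`, a
SeedSequence over the master seed and a stage tag), so the whole chain is
reproducible byte-for-byte.

## Evaluation

The blind report contains exact agreement with the consensus template on
the test partition, the 3 × 3 ordinal confusion matrix (rows: consensus,
columns: prediction), and the critical-error count — predictions two
grades away from consensus, i.e. the (1,3) and (3,1) confusion cells. On
the reference experiment (n = 126, master seed 42, examiner confusion 0.1)
the evolved network agrees with the consensus on 19/19 blind-test images
with zero critical errors; accuracy varies with the master seed but stays
at or above the high-80s percent range under the default conditions.

## Problem sizes and numerical choices

The reference experiment uses 126 images of 256² px; feature extraction
costs ~0.3 s per image and the evolutionary search a few hundred cheap
network trainings, so the full chain completes in a few minutes on one
CPU. Known degenerate inputs are handled explicitly: constant images
(standardisation error; all-false gradient map; single watershed region),
empty regions and masks too small for a GLCM offset (degenerate-input
errors), non-finite features (an extraction error naming the feature), and
divergent training (an error naming the learning rate).

## Limitations

The 36-variable registry reconstructs the named descriptor families
(circularity, GLCM texture, watershed, regional statistics); it is a
design choice, not a canonical list. The ICM/blastocoel interior is kept
as one compartment — no operator separates them — and the ICM is located
only for pose normalisation. Performance numbers are synthetic-data
properties; transferring the pipeline to real micrographs would at minimum
require re-fitting the reduction and re-running the evolutionary search on
real feature tables.
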