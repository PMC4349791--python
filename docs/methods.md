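# Methods

This note documents the models and procedures implemented in
`spineret`, the parameters that matter, the numerical choices made
where the design was open, and what the synthetic benchmark does and
does not demonstrate.

## Vertebra shape representations

A vertebra boundary is an ordered nine-landmark configuration (9-APR):
landmarks 1/3 are the lower anterior/posterior corners, 4/6 the upper
posterior/anterior corners, 2/5 the lower/upper edge midpoints, 8 the
anterior midpoint, and 7/9 the upper/lower anterior-osteophyte points.
A normal vertebra has 7 coincident with 6 and 9 with 1; any spur
displaces 7 and/or 9 anteriorly. The canonical boundary polygon
traverses 1→2→3→4→5→6→7→8→9→1 (clockwise in image coordinates, x right
and y down, 0-based pixel centers, sub-pixel values allowed) with
coincident points collapsed. The traversal and start point are a fixed
convention: the Fourier descriptors are start-point invariant, so the
choice is internally irrelevant, but fixing it enables exact regression
tests.

The B-spline representation (B-SR) places 27 points equally spaced by
arc length on the canonical polygon and treats them as control points
of a closed (periodic) uniform cubic B-spline — control-point semantics,
i.e. the curve approximates rather than interpolates the 27 points; the
knot vector is not dictated by the landmark scheme, and uniform
periodic knots are the simplest closed-curve choice. The curve is
evaluated densely and resampled to 128 arc-length-uniform points (a
power of two, so signature DFTs need no padding).

Generalized Procrustes alignment centers each configuration, scales it
to unit Frobenius norm, and iterates rotation-to-mean / mean
re-estimation to a 1e-12 mean-change tolerance. The aligned set is then
rescaled into the mean's frame so that the mean of the aligned shapes
*is* the stored unit-norm mean exactly — PCA on the aligned set is then
consistent with the stored mean without a second centering convention.

## Active shape model

The shape model is a PCA of aligned landmark vectors keeping the
smallest number of modes reaching 98% cumulative variance (eigenvector
signs fixed by making the largest-magnitude component positive, for
reproducibility). The profile model stores, per landmark, the mean and
covariance of the first-difference gray profile sampled along the
boundary normal, normalized by its sum of absolute values; covariances
from small training sets are routinely singular, so Mahalanobis
distances use a ridge-regularized inverse (ridge 1e-6).

Search alternates profile matching and model regularization. Defaults:
profile half-length k = 8 (17 samples per whisker), search range
m = 4 px, at most 50 iterations, convergence when at most 5% of
landmarks move more than 1 px. Two choices here came out of the
parameter-recovery experiments rather than textbook defaults:

* **Rigid-first search.** The first 8 iterations fit only the
  similarity pose (shape parameters held at zero) with a wider search
  range (6 px). With a deformable model active from the start, a ±5 px
  initialization offset routinely locked the shape constraint onto a
  mis-posed local minimum (≈60–70% of test images under 2 px mean
  error); absorbing the offset rigidly first raises that to 80–100%
  across seeds.
* **k = 8 rather than 6.** The longer whisker profile makes the corner
  and osteophyte-point profiles more discriminative on blurred, noisy
  renderings; with k = 6 the recovery rate was consistently lower.

The integer profile-cost minimum is refined by a parabola through the
three neighbouring costs (sub-pixel step, capped at ±0.5 px), which
lowers mean landmark error by ~0.1–0.2 px. The search is single
resolution and needs a pose initialization; automatic vertebra
localization is out of scope. Both the 9 anatomical points and the 27
B-SR control points can serve as the ASM landmark set.

Residual limitation: a *slight*-grade spur protrudes only ~2 px beyond
the corner, comparable to the rendering noise, so normal-versus-slight
ambiguity occasionally costs one landmark several pixels; per-image
mean recovery error then hovers around the 2 px mark and the fraction
of images under 2 px varies noticeably with the generator seed.

## Region-based descriptors

The segmented mask is converted to an exact Euclidean distance
transform (pixel-center metric; if a mask has no background at all the
image border counts as background). All intensity-based descriptors
operate on the EDT rescaled to [0, 1]; the Radon descriptor operates on
a skeleton derived from the EDT.

* **Skeleton.** Watershed ridge extraction on the negated EDT, seeded
  at its regional maxima, restricted to the foreground and unioned with
  the maxima plateaus themselves, then thinned to 1 px. The plateau
  union matters: an elongated body has one connected distance-maximal
  medial band, which yields a single catchment basin and hence no ridge
  line, yet is exactly the medial structure the skeleton must contain.
* **GW.** Complex Gabor bank with dyadic frequencies f_j = 0.25/2^j
  cycles/px (J = 4 levels), orientations {0°, 45°, 90°, 135°}, envelope
  std σ = 0.56/f_j (≈ one octave), aspect γ = 0.5, kernels truncated at
  3σ. One feature per frequency level: the mean over pixels and
  orientations of (|even response| + |odd response|)/2. A
  per-orientation variant (J × 4 features) is available. Kernels larger
  than the image are rejected, which bounds usable J by image size
  (level 3 kernels are 109 px, hence the 128 px default image).
* **GLCM.** Intensities uniformly quantized to G = 8 levels; joint
  counts for offsets (0,1), (1,0), (1,1), (1,−1) symmetrized and
  averaged; six statistics in fixed order — contrast Σ(i−j)²p, energy
  Σp², entropy −Σp log₂p (bits), homogeneity Σp/(1+|i−j|), correlation
  Σ(i−μᵢ)(j−μⱼ)p/(σᵢσⱼ) (defined as 0 for a degenerate distribution),
  variance Σ(i−μᵢ)²p.
* **RT.** For each integer angle 0–179°, each skeleton pixel's mass is
  projected onto r = −(x−cₓ)sinθ + (y−c_y)cosθ and split linearly
  between the two nearest integer bins. Forward splitting conserves the
  per-angle projection mass exactly (image-rotation implementations do
  not), and the projection center sits on an integer pixel so
  axis-aligned structures land in single bins. The per-angle feature is
  the mean of the projection over its non-zero support (the mean over
  all bins is constant in θ by conservation and carries no
  information); an empty projection contributes 0.
* **OH.** Gradients from the 1×3 filters [−1, 0, 1] and its transpose;
  directions folded into [0°, 180°) and accumulated magnitude-weighted
  into 18 bins of 10° over interior pixels (a count mode is available;
  magnitude weighting is the default because it degrades gracefully
  under noise).

## Contour-based descriptors

Boundaries are resampled to N = 128 arc-length-uniform points. The
signature centroid is the mean of the boundary samples, which makes the
complex-coordinate signature exactly zero-mean (that is what removes
translation); on arc-length-uniform contours it tracks the area
centroid closely.

* **GSP** (seven values): shoelace area, polygonal perimeter,
  compactness 4πA/P², eccentricity from the polygon's central second
  area moments, convexity A/A_hull, rectangularity A/A_minrect, and the
  minimal-rectangle aspect ratio. The member set is a pragmatic choice
  of standard geometric descriptors; no canonical list exists.
* **Shape signatures**: central distance r(n) = |P_n − C| and complex
  coordinates z(n) = (x_n − Cₓ) + i(y_n − C_y); |z| ≡ r pointwise.
* **Fourier descriptors**: DFT with 1/N normalization (any consistent
  convention cancels under the ratio normalizations); phases discarded
  (rotation and start-point invariance). CD keeps frequencies
  1..N/2−1 — the signature is real, so only N/2 frequencies are
  informative — divided by the DC magnitude (scale invariance). CC
  drops the DC term and divides the remaining magnitudes by the first
  positive-frequency coefficient ("second descriptor" read as frequency
  +1), which is itself omitted. Descriptor lengths are therefore 63
  and 126 at N = 128. A Fourier descriptor *of the GSP vector* is not
  implemented: the GSP is not a sequential signal and no construction
  is defined for it; GSP is used as a plain feature vector.

## Gating classifier

Features are min-max normalized per dimension with statistics from the
training folds only (constant dimensions map to 0; out-of-range test
values are clipped). The network has one hidden layer of 20 logistic
units, softmax output, cross-entropy loss, adam with learning rate
0.01 (full-batch steps on the small feature sets involved; the default
0.001 left the posteriors visibly under-trained at 500 epochs), at most
500 epochs, patience 25. Training uses stratified 5-fold cross
validation with standard semantics — fit on four folds, score (accuracy
and macro one-vs-rest AUC) on the held-out fold — and deploys the
fold with the best held-out AUC (lowest fold index on ties). An
inverted variant (train on one fold, test on four) exists behind a
flag for comparison. AUC uses the rank (Mann–Whitney) formulation with
ties counted one half, which agrees exactly with exhaustive pairwise
comparison; multiclass AUC is the macro one-vs-rest average.
Prediction runs through the stored weights directly, so a serialized
model is a self-contained JSON document independent of the training
backend.

## Retrieval and evaluation

The archive stores raw feature vectors with a shared min-max normalizer
and per-dimension standard deviations σ_k of the normalized features.
The default similarity is the weighted city-block distance with weights
1/(σ_k + 1e-9); plain city-block and chi-square
Σ(q−i)²/(q+i+ε) are selectable. Ranking is ascending by distance with
ties broken by record id, so results are total and reproducible. A
query that is an archive member is excluded from its own candidate list
(leave-one-out evaluation). Under the gated architecture the classifier
first predicts the query's class and only archive records
*pre-classified* to that class are ranked; if gating empties the
candidate set the result is empty with an explicit status.

Pr@M is the percentage of the M topmost hits sharing the query's true
class; when gating leaves fewer than M candidates the missing positions
count as irrelevant (the denominator stays M). A_GS is the arithmetic
mean of Pr@5, Pr@10, Pr@15, Pr@20.

## Synthetic data

The generator emulates a lateral-view vertebral body as a convex
quadrilateral (width 0.42 and height 0.30 of a 128 px canvas) with
per-corner jitter of up to 3% of the body width — enough variation for
the shape PCA to learn non-degenerate modes. A traction spur is a
horizontal anterior protrusion of the osteophyte point by s times the
anterior edge length; a claw spur is the same length bent 30° toward
the adjacent disk; claw-traction combines a claw at the upper and a
traction spur at the lower point. Severity grades map to
s = 0.05/0.12/0.20 (slight/moderate/severe); lumbar corner spurs use
s = 0.15. These values are measurable stand-ins for qualitative
radiological grading and are configurable. Random draws are consumed in
class-independent order, so for a fixed seed the severity grades of one
morphology differ only in spur length — severity monotonicity holds
seed by seed, exactly.

Rendering fills the boundary polygon at intensity 0.75 on a 0.25
background, blurs with a Gaussian (σ = 1 px) and adds Gaussian noise
(σ = 0.05 intensity units), clipping to [0, 1]. Placement jitter
(rotation ±6°, scale 0.92–1.08, translation ±3 px) provides pose
variation. Everything is keyed to a single dataset seed through spawned
child seeds; regeneration is byte-identical.

What the benchmark does **not** emulate: soft-tissue and rib clutter,
exposure gradients, multi-vertebra context, inter-reader annotation
variability, and the continuous severity spectrum of real osteophytes.
Passing results therefore demonstrate the internal correctness and the
architectural claim (gating helps when the classifier is informative),
not clinical-grade retrieval accuracy; absolute Pr@M values on real
radiographs are not comparable to the synthetic ones.

## Pre-processing

Median filter (window 3, edge-replicated) followed by CLAHE on an
8×8 tile grid with clip limit 0.01, both switchable off; a gamma mode
exists as an alternative. This is a deliberately simple, testable
enhancement chain standing in for adaptive non-linear contrast
adjustment; a constant image passes through unchanged. Enhancement is
applied identically before ASM training and before search.

## Problem sizes and determinism

The packaged experiments use 22 images per class (cervical 220, lumbar
88) so that leave-one-out retrieval at M = 20 never exhausts a class;
the ASM recovery experiment uses 40 training and 10 test images at
noise 0.05 with ±5 px translation-perturbed initialization. All
randomness flows from explicit integer seeds (dataset seed, classifier
seed, experiment seed); two runs with the same configuration produce
byte-identical tables.
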