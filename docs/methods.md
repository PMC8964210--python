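# Methods

## Problem setting

A Pap-smear screening pipeline receives segmented single-cell images: an
RGB crop, a binary nucleus mask, a binary cytoplasm mask (disjoint; their
union is the cell region, background already removed), and one of seven
morphology labels — three normal classes (preliminary squamous, moderate
squamous, columnar) and four precancerous/cancerous grades (preliminary,
intermediate and last-stage dysplastic, and carcinoma in situ).  The
package classifies such cells and quantifies how much a wrapper
feature-selection step improves the classifier.

## Feature extraction

**Morphometrics (13 scalars).**  Conventions are chosen so every value is
exactly reproducible by pixel counting:

- `nucleus_area` = nucleus pixel count; `cell_area` = nucleus + cytoplasm
  pixel count; `nucleus_cell_ratio` = their quotient (the cytologist's
  N/C ratio).
- `nucleus_length`/`nucleus_width` = larger/smaller side of the
  axis-aligned bounding box, so `aspect_ratio = W/L ∈ (0, 1]`.
- `nucleus_perimeter` = number of nucleus pixels with at least one
  4-neighbor outside the mask (image border counts as outside).  A 10×10
  square therefore has perimeter 36, and roundness `4πA/P²` evaluates to
  4π·100/36² ≈ 0.9696 on it.  Note that under this boundary-pixel
  convention a rasterized disk scores ≈ 1.26 (the count under-measures
  diagonal boundary); roundness is a *relative* shape index — disks score
  higher than elongated ellipses at any radius, and the value is stable
  (< 5% drift) under doubling of scale — not an absolute circularity
  calibrated to 1.
- `nucleus_homogeneity` = energy `Σ pᵢ²` of the normalized 256-bin gray
  histogram of nucleus pixels: 1 for uniform intensity, → 1/256 for a flat
  histogram.
- brightness/extrema are plain means/max/min of the luma image
  (0.299 R + 0.587 G + 0.114 B, rounded half-up).

**BHF texture.**  The binary-histogram-Fourier block is built like the
LBP-histogram-Fourier family of descriptors.  At every pixel whose full
sampling neighborhood lies inside the cell mask (square erosion by
⌈R⌉), a P-bit code compares each of P circular neighbors (radius R,
bilinear interpolation) with the center; ties count as 1, with a 1e-6
tolerance so constant regions yield all-ones codes exactly.  Uniform codes
(≤ 2 circular transitions) are histogrammed by (ones-count n, rotation
index r); all-zeros, all-ones and non-uniform codes get three scalar bins.
The histogram is normalized (rows + three bins sum to 1), each ones-count
row is DFT'd along r, and magnitudes of frequencies 0..P/2 are kept —
38 values for the default P = 8, R = 1.  Image rotation cyclically shifts
each row, so the magnitudes are rotation-invariant; for 90° rotations the
invariance is exact because the sampling stencil maps onto itself.

**Feature groups.**  For subset selection the vector is treated as 14
groups: the 13 scalars individually and the whole BHF block as one unit.
The `paper7` preset keeps nucleus area, roundness and brightness, cytoplasm
brightness, cell area, the N/C ratio, and the BHF block.

## Classifier

Fuzzy C-means with the standard Bezdek updates, run on z-scored features
(training statistics stored in the model — raw units mix pixels, gray
levels and ratios).  `n_clusters` defaults to 7, one per class; restarts
(`n_init`, default 5) are seeded from the master seed and the best final
objective is kept; the objective trace is non-increasing within a restart
by construction.  Cluster → class labels come from the majority class of
the hard-assigned training points (ties toward the earlier class; empty
clusters fall back to the global majority with a warning), prediction is
argmax membership.

**Fuzziness default m = 1.5.**  With many clusters in a moderate-
dimensional standardized space, large m makes the grand-mean configuration
attracting: initialized *at the true class centroids* of 7 well-separated
blobs in 7 dimensions, m = 2 collapses to one effective cluster
(hard-assignment purity 0.17) while m = 1.5 stays put (purity 0.92).  The
default is therefore 1.5 — fuzzy, but inside the stable regime; m is
configurable for anyone wanting the textbook 2.0, and the m → 1 limit
reproduces nearest-centroid assignment (verified at m = 1.05).

## Feature selection

A quantum-behaved swarm over binary masks of the 14 groups.  Per particle
and dimension, with attractor `p = φ·pbest + (1−φ)·gbest` (φ ~ U(0,1)) and
`mbest` the mean of all personal bests:

    x' = p ± β·|mbest − x|·ln(1/u),  u ~ U(0,1), sign w.p. ½,

with β annealed linearly from 1.0 to 0.5; bits are Bernoulli(sigmoid(x')),
all-zero masks are repaired by switching one random bit on.  The swarm is
velocity-free.  Defaults: 20 particles, 50 iterations, one particle seeded
all-ones so the selected subset can never score below the full feature set
on the internal split.

**Fitness** = macro-F1 of the FCM classifier on a stratified 70/30
validation split of the training data, minus `λ·(bits set)/d` with
λ = 0.01.  The split is fixed per run (derived from the swarm seed), so
fitness is a deterministic function of the mask — this makes global-best
monotonicity meaningful and allows caching of repeated masks.  The penalty
is small enough never to outweigh a 1-class F1 difference and simply
prefers the smaller of two equal-F1 subsets.

Verification: an exhaustive oracle evaluates all 2^d − 1 nonempty masks
(d ≤ 16; ties toward fewer bits, then the lexicographically smaller bit
tuple).  On random d = 10 fitness tables the swarm (30 × 100) reaches
within 2% of the exhaustive optimum in ≥ 9/10 seeds.

## Evaluation protocol

Confusion matrices (rows = actual), one-vs-rest precision/recall/F1 with
*macro* averaging (classes are imbalanced; an unweighted mean does not let
frequent classes mask rare dysplasia grades), Cohen's kappa, and a
Brier-style membership error `mean ‖uᵢ − onehot(yᵢ)‖²/K` as the MSE
measure.  The seven classes collapse to a binary normal-vs-cancerous call
(cancerous = the four dysplasia grades is the positive class) for
accuracy/sensitivity/specificity.  Zero-division conventions: a
never-predicted class gets precision/F1 0 with a warning, an undefined
binary rate is reported as None, kappa at chance agreement 1 is 0.

Data handling: seeded stratified 70/30 split (classes with one sample are
rejected), stratified k-fold CV with k = 12 by default (k is reduced to
the rarest class count with a warning).  `run_experiment` chains the
stages — split, all-features FCM, swarm selection on the training portion
only, FCM on the selected groups, both evaluated on the same held-out test
set, optionally a 1-NN baseline — and echoes every derived seed.

## Synthetic data

The generator emulates the dysplasia progression with two nested
rasterized ellipses.  Per class it fixes nucleus/cytoplasm semi-major
radius (mean ± sd, pixels), gray level (mean ± sd), texture amplitude and
an eccentricity range; the defaults encode: nucleus radius strictly
increasing (13 → 17 → 21 → 24 px) and nucleus gray strictly decreasing
(95 → 82 → 70 → 55) from mild dysplasia to carcinoma in situ, cytoplasm
shrinking for the severe grades (40 → 36 → 30 px), against normal classes
with small bright nuclei (7–10 px, gray 100–120).  These numbers are free
parameters of the emulation — the source collections publish no per-class
morphometry — chosen once to give overlapping-but-separable classes at
128×128 px (the 0.197 µm/px scale of the real material is carried as
metadata only).  Pixel values are class mean + N(0, sd) + a random-
orientation sinusoid scaled by the texture amplitude, clipped to [0, 255],
gray replicated to RGB.  Nucleus placement redraws up to 100 times before
raising.  Per-image RNG substreams are keyed by (seed, class index, image
index), so generation order cannot change outputs.  Two presets reproduce
the published per-class counts of the two emulated collections (totals
1614 and 1500).

What this does *not* model: overlapping cells, debris, staining variation,
chromatin clumping, or any correlation structure of real Herlev-style
morphometry.  Passing tests therefore demonstrate correctness of the
pipeline's computations and the selection dynamics, not clinical accuracy
on real smears.

The planted-feature benchmark (`planted_feature_groups`) is a feature-space
analogue: 7 informative single-column groups (class-mean offset 3.0 sd, one
class each) plus 7 pure-noise groups, 24 samples per class.  It tests
whether wrapper selection recovers a known informative set.

## Problem sizes and numerics

The test suite and the acceptance script run everything at desk scale:
selection benchmarks use 10 seeds with the default 20 × 50 swarm on
168 × 14 planted matrices; the end-to-end experiment uses 30 cells per
class; the wrapper fitness uses a lighter FCM setting (2 restarts, 150
iterations) than the final model fit, a standard wrapper economy since
fitness only ranks masks.  FCM stops on |ΔJ| < 1e-5; memberships at zero
distance are hard-assigned; duplicate initial centroids are jittered by
1e-6.  All randomness flows from explicit seeds; repeated runs are
bit-identical.

## Known limitations

- FCM remains initialization-sensitive in high dimensions even at m = 1.5;
  with all 51 columns (13 + 38 BHF) the unselected classifier often merges
  classes.  The package reports this honestly — it is the "without
  selection" arm of the comparison, and the gap is the method's point.
- The BHF block's 90°-rotation invariance is exact; arbitrary-angle
  invariance holds only approximately through the bilinear sampling.
- Roundness is a relative index (see above), not calibrated to 1 for
  digital disks.
- The binary normal/cancerous collapse assumes the canonical seven-class
  taxonomy; reports on other label sets omit it.
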