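# Methods

## The segmentation model

`hlfseg` treats membrane detection in 2-D EM sections as supervised
per-pixel classification with features drawn from three levels of image
structure. The assumptions behind the design:

- membranes are thin (a few pixels), dark, elongated structures separating
  textured, brighter cell interiors;
- pixels within a SLIC superpixel are nearly homogeneous, so a superpixel
  is a meaningful aggregation unit and one sampled pixel can represent it
  during training;
- misclassifications of pixel-level classifiers cluster at boundaries and
  inside dark organelles, which superpixel statistics, neighborhood
  context and shape-based postprocessing can counteract.

Each section is processed independently; no 3-D consistency is modeled.

## Preprocessing

Global histogram equalization (cumulative-histogram transform, 256 bins,
matching the 8-bit heritage of EM data) followed by Gaussian smoothing
with σ = 1 px. Equalization is global rather than local: simpler, and the
synthetic and typical EM sections have no strong illumination gradients.
Both steps are configurable (`preprocess.equalize`, `preprocess.sigma`).
All filtering in the package uses reflective boundary handling, avoiding
zero-padding halos at membrane-dense image borders.

## SLIC oversegmentation

Localized k-means in joint intensity–position space. Centers start on a
regular grid with interval s = √(N/k) (an interval must have units of
pixels, hence the square root of the per-superpixel area), perturbed to
the lowest-gradient position in a 3×3 neighborhood; assignment is
restricted to a 2s × 2s window per center; 10 assign/update iterations.
The distance between center c and pixel j is

    D = (d_c / N_c)² + d_s / N_s,

with d_c = |I_j − I_c|, d_s the Euclidean position distance, N_s = s, and
N_c = 0.1 intensity units (the compactness knob; smaller N_c hugs
intensity edges harder). The canonical form
√((d_c/N_c)² + (d_s/N_s)²) is available via
`slic.distance_form = "squared"`; the default asymmetric form is the
package's primary definition and behaves equivalently in practice at
these scales. Ties in assignment go to the lowest center index, making
the algorithm fully deterministic. A final pass relabels 4-connected
fragments smaller than s²/4 into adjacent regions, guaranteeing a total
partition with connected, consecutively numbered regions.

The default superpixel count scales with image area at ~9500 per 512×512
section (grid interval ≈ 5.3 px), the operating regime the method is
designed for; membranes ~3 px wide and cells tens of pixels wide are then
well resolved. On 256×256 synthetic sections this gives k ≈ 2375.
Measured on the synthetic benchmark (5 seeds, s = 8), boundary recall —
the fraction of true membrane pixels within 2 px of a superpixel
boundary — averages ≈ 0.92.

## The 34-channel pixel feature bank

Channel order is frozen (see `features_pixel.CHANNEL_NAMES`); sample
vectors are meaningless without it. Parameter choices where a filter
family needs them: Hessian eigenvalues at σ = 1 (Gaussian derivatives);
structure tensor with derivative scale 1 and integration scale 3;
difference of Gaussians σ-pair (1, 2); classical 4-quadrant 5×5 Kuwahara
(ties to the first quadrant in NW/NE/SW/SE order); 3×3 Laplacian; Gaussian
gradient magnitude at σ = 1. The edge map feeding the two non-local
features is Canny at σ = 1 with hysteresis thresholds (0.1, 0.2).

Ray features (12 channels): from each pixel, rays are cast in the four
axis directions until the first Canny edge pixel; each ray contributes the
distance to the hit (capped at 64 px), the Sobel gradient magnitude at the
hit, and the cosine between ray direction and gradient direction at the
hit. A ray that reaches the cap or the border without a hit reports the
cap distance and zeros. These descriptors encode the size and wall
orientation of the enclosing region — informative for distinguishing
membrane interiors from organelles.

Radon-like feature (1 channel): along scanlines in four directions (0°,
45°, 90°, 135°), each line is split at edge crossings and every pixel gets
the mean image intensity of its segment; the channel is the mean of the
four direction maps. This pools dark membrane intensity along membranes
and bright cytoplasm across cell interiors.

Both non-local features are principled reconstructions of descriptor
families from the tracing literature, not numerical reproductions of any
particular implementation.

After computation every channel is min-max normalized to [0, 1] over the
image (constant channels map to zero), so superpixel means aggregate
commensurate quantities.

## Hierarchical features and sampling

The superpixel block holds the mean of each of the 34 channels over the
superpixel plus the Shannon entropy (bits) of its intensity histogram with
32 bins — superpixels at the default granularity hold ~30–100 pixels, so
256 bins would starve the histogram. The context block holds mean
intensity, mean Sobel gradient magnitude and intensity variance over the
union of the pixels of the first-ring neighbors (statistics of the union,
not averages of per-neighbor statistics, so large neighbors weigh
proportionally; an isolated superpixel falls back to its own pixels).
Aggregation is exactly conservative: size-weighted superpixel channel
means reproduce global channel sums to 1e-9·N, which the tests assert.

Training samples are one uniformly random pixel per superpixel, labeled
by the ground-truth value at that pixel (not by superpixel majority — the
classification target is per-pixel). The 72-vector is the concatenation
[pixel block at the sample | superpixel block of its region | context
block of its region].

## Classifier

A Random Forest with 100 trees, √72 ≈ 8 features per split, bootstrap
resampling, unlimited depth, and out-of-bag error as the internal
generalization estimate (scikit-learn's implementation behind a thin
model wrapper). The wrapper accepts any estimator with the
`fit`/`predict_proba` contract, so alternative classifiers can be swapped
in for comparisons. Dense prediction assembles the 72-vector for every
pixel (pixels of one superpixel share the superpixel and context blocks)
and is chunked to bound memory.

## Postprocessing

Otsu thresholding of the probability map (mean and isodata also
available; a constant map yields an empty foreground), then iterative
removal of 8-connected foreground components matching any rule in an
OR-of-conjunctions rule set. Defaults: area < 100 px (specks), or
solidity > 0.7 AND eccentricity < 0.9 AND area < 1000 px (compact round
blobs — organelle false positives; genuine membrane nets are large,
low-solidity and elongated). Euler number is available as a rule property
but unused by default. Removal is component-atomic and monotone, iterated
to a fixpoint (≤ 10 passes).

## Metrics

All three metrics take membrane = 1 and are in [0, 1]; identical inputs
score 0.

**Pixel error** = 1 − max over a 256-step threshold sweep of the
membrane-class F-score.

**Rand error** = 1 − max over the sweep of the pair-counting F-score
between the region partitions induced by prediction and ground truth.
Regions are 4-connected components of non-membrane pixels; membrane
pixels get label 0. Pixels that are membrane in the *ground truth* are
excluded from pair counting entirely (the thin-boundary convention);
pixels predicted as membrane remain but are never co-clustered — this
keeps an all-membrane prediction from scoring perfectly. The pair counts
are verified in the tests against an O(n²) enumeration over all pixel
pairs.

**Warping error**: the ground truth is deformed toward the prediction by
repeatedly flipping pixels that (a) disagree with the prediction, (b) are
simple points of the current warped image, and (c) lie within 2 px
(Euclidean) of the original ground-truth boundary; flips proceed in
row-major order until none is legal, and the remaining disagreement
fraction is returned. Simple-point status uses foreground connectivity 4
and background connectivity 8, decided by component counting in the 3×3
patch via a precomputed lookup table. Cells outside the image belong to
neither class (a ternary patch state), so border pixels are judged on the
clipped patch — padding with phantom background would let flips merge
background regions that are genuinely separate inside the image. The
tests assert that warping never increases disagreement and preserves
foreground (4-connected) and background (8-connected) component counts
exactly.

The evaluation report computes pixel and Rand error over the shared
sweep and the warping error at the pixel-error-optimal threshold.

## Synthetic data generator

`SyntheticSpec` defaults define the benchmark conditions: 256×256 px,
12 cells, membrane width 3 px, cytoplasm mean 0.7, membrane mean 0.15,
per-cell texture SD 0.05, additive noise SD 0.03, blur σ = 1 px, one
organelle per cell with probability 0.5 at intensity 0.4. Cell geometry is
a Voronoi tessellation of random seeds; membranes are the Voronoi edges
dilated to width; texture is a smoothed Gaussian field with per-cell gain.
Intensities emulate the dark-membrane/bright-interior contrast and
granularity of stained ssTEM at a moderate noise level; the membrane
fraction of the mask lands near 0.07, within the 5–15% range typical of
dense neuropil. All randomness flows from one integer seed;
identical specs give bit-identical images.

What the generator does **not** emulate: section-to-section deformation,
staining gradients, ice/dust artifacts, mitochondrial cristae and vesicle
clutter at realistic density, membrane thickness variation, or
electron-optical noise statistics (noise is Gaussian, not Poisson-like).
Passing tests on this benchmark demonstrate the pipeline's mechanics —
feature validity, classifier wiring, metric correctness — not performance
on real tissue.

A consequence measured by `scripts/acceptance.py`: on these synthetic
conditions the task is easy enough that the pixel-only 34-feature
classifier already reaches Rand errors near 10⁻³, leaving almost no
topological errors for the superpixel and context blocks to repair. The
hierarchical features reliably improve the *warping* error (their
boundary adherence removes topological defects) while the pixel-only
block tends to win the *pixel* and *Rand* errors by small margins at this
noise floor. On real EM, where pixel-level prediction is far noisier,
the hierarchical combination is designed to pay off in Rand error as
well; the synthetic benchmark cannot demonstrate that regime, and the
benchmark conditions were deliberately not tuned to manufacture it.

## Problem sizes

The test suite and acceptance script run entirely on synthetic data:
128×128 sections for unit-level checks, 256×256 for the benchmark runs;
the feature-level comparison uses 5 training and 5 held-out sections per
seed for 3 seeds with 100-tree forests. These sizes keep a full
reproduction in the minutes range on a single CPU while preserving the
granularity relations (membrane width ≪ superpixel interval ≪ cell
diameter) of the full-scale setting.

## Known limitations

- Global histogram equalization; no CLAHE or destriping.
- The ray and Radon-like features are reconstructions (see above).
- The SLIC distance uses one intensity channel; no color support.
- Postprocessing thresholds are engineering defaults validated on
  synthetic data, not learned.
- The warping-error greedy flip order (row-major) is one deterministic
  choice among the valid orders; different orders can leave slightly
  different residuals in pathological ties.
- No probability calibration and no feature-importance reporting.
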