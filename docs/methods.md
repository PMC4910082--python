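# Methods

This note documents the models, conventions and numerical choices
behind `histotex`, and what the synthetic fixtures do and do not show
about real histology data.

## Canonical image representation

All descriptors consume a 2-D `float64` raster in [0, 1].  8-bit
inputs are divided by 255; RGB is reduced with ITU-R BT.601 luma
weights (0.2989, 0.5870, 0.1140), the convention of Matlab's
`rgb2gray`, since the pipeline is modelled on a Matlab-based
toolchain.  The weight choice matters only at the fraction-of-a-percent
level for downstream accuracies; it is centralized in
`image_io.LUMA_WEIGHTS`.

## Descriptor families

**Histogram moments.** Computed directly on the pixel sample rather
than a binned histogram — the values agree in the fine-bin limit and
this removes the bin count as a free parameter.  `histogram_lower` is
[mean, population variance, μ₃/σ³, non-excess kurtosis μ₄/σ⁴, raw μ₅];
`histogram_higher` is the raw central moments μ₂…μ₁₁ and is exactly
invariant to adding a constant to all pixels.  Zero-variance images
take skewness = kurtosis = 0 so degenerate background tiles stay
finite.

**LBP-HF.** The (8, 1) ring samples axial neighbours exactly and
diagonal neighbours by bilinear interpolation; the threshold is
neighbour ≥ centre.  Uniform patterns (≤ 2 circular transitions) with
n = 1…7 set bits form orbits of eight rotations; the DFT magnitudes at
frequencies 0–4 of each orbit histogram, plus the all-0, all-1 and
pooled non-uniform bins, give 38 features.  A right-angle image
rotation permutes the ring cyclically, so these features are invariant
to it up to float round-off (the test tolerance is 1e-6; observed
differences are ≈ 1e-16).

**GLCM.** Intensities are quantized into 8 equal-width bins spanning
the image's own [min, max] (Matlab `graycomatrix` defaults; the level
count is a keyword).  For each displacement d ∈ 1…5 the four
directional matrices — per-axis offsets (0, d), (−d, d), (−d, 0),
(−d, −d) — are symmetrized, averaged, normalized, and summarized by
contrast, correlation, energy and homogeneity.  The pair counting is
implemented directly with array slicing because scikit-image's
`graycomatrix` measures diagonal displacement along the direction
vector (rounding d·cos 45°), which does not reproduce the per-axis
step convention used here; a brute-force pair-enumeration oracle in
the test suite checks the counts exactly on small images.  A constant
image yields a single-cell matrix: contrast 0, energy 1, homogeneity
1, and correlation 1 by the zero-variance convention.

**Gabor.** Six orientations × six wavelengths (2–12 px/cycle, the
scale range of nuclei, cells and fibres at ~0.5 µm/px).  The envelope
uses σ = 0.56 λ along the wave axis (one-octave half-response
bandwidth) and aspect ratio 0.5; the cosine component is DC-corrected
with an envelope-weighted offset so a constant image responds ≤ 1e-6;
kernels truncate at 3σ of the wider axis and the image is
reflect-padded, so the per-wavelength orientation-averaged magnitude
means are invariant to right-angle rotations.  The largest kernel is
83 px, which sets the minimum image size for this family.

**Perceptual.** Tamura-style definitions with the usual defaults, all
exposed as keywords: coarseness scans window sizes 2¹…2⁵ and averages
the winning size over interior pixels only (border pixels' differences
are dominated by reflection padding and are excluded from the mean);
contrast is σ/(μ₄/σ⁴)^¼; directionality measures the concentration of
the 16-bin gradient-orientation histogram over pixels above 12% of the
maximum Prewitt gradient magnitude, rescaled so a uniform histogram
scores 0 and a point mass 1; line-likeness averages the orientation
cosine of edge-pixel pairs 4 px apart along the local edge direction;
roughness = coarseness + contrast.

**Combined sets.** Families concatenate in their accuracy-rank order
(histogram-lower, LBP, histogram-higher, GLCM, perceptual, Gabor).
When histogram-higher joins (`best3` onward) its moments μ₂…μ₅ are
dropped as duplicates of histogram-lower's variance/skewness/kurtosis/
μ₅; this is the only de-duplication under which the subset sizes sum
to the documented 74 dimensions of `best5`, and anyone comparing
against other implementations should check this rule first.

## Classifiers

All kinds standardize features to zero mean and unit *population*
standard deviation (constant columns map to zero).  Standardization is
fitted on the training folds only and applied to test folds — fitting
it on the full matrix before splitting leaks test statistics into
training and is deliberately not done, even though it is the more
common description of this kind of pipeline.

SVMs use C = 1 and, for the rbf kernel, kernel scale √d (γ = 1/d on
standardized features) — reasonable defaults in the absence of
stronger prior information; both are hyperparameters of
`ClassifierSpec`.  Multiclass decisions use one-vs-one binary SVMs
with hinge-loss ECOC decoding, and committee scores are the softmax of
the negated per-class aggregate losses, so score rows sum to 1 and
argmax equals the decoded prediction (ties resolve to the lowest class
id).  1-NN scores are the one-hot vector of the nearest neighbour's
class, which makes its one-vs-all ROC curves degenerate two-point
curves; this is documented rather than special-cased.  RUSBoost is
SAMME boosting (100 trees, depth ≤ 5, learning rate 0.1) where each
round fits on a class-balanced random undersample; it is fully
reproducible under the spec seed.

## Evaluation protocol

10-fold cross validation with random, unstratified folds whose sizes
differ by at most one — with balanced classes and hundreds of samples
the fold class proportions stay stable without stratification.  One
pass over 10 folds is the default (`repeats` exists as a knob);
accuracy is the unweighted mean of fold accuracies, the pooled
confusion matrix aggregates all held-out predictions, and one-vs-all
AUCs are macro-averaged.  The full benchmark grid crosses 4
classifiers × 6 pure feature sets × {two-class, eight-class} = 48
experiments.

## Segmentation geometry

Tile top-left offsets are `round(i · (extent − tile)/(n − 1))` per
axis, which spaces n tiles evenly, places the first at 0 and ends the
last exactly at the image edge; for 5000-px images with 150-px tiles
and n = 100 the stride is a non-integer 48.99, so per-index rounding
is unavoidable and exact tile positions are a convention of this
package.  The label grid is smoothed by a modal (majority) filter —
the categorical analogue of a median filter, since the arithmetic
median of class ids is meaningless — with ties keeping the original
label.  Classification maps are coloured first and then bicubically
enlarged; probability maps are upscaled per channel.

## Synthetic data

The generator emulates the statistical design of the 8-class
histology tile benchmark: eight families with distinct second-order
structure — mid-scale blob fields (tumour-like), oriented gratings
(fibrous stroma), a grating/blob mixture (complex stroma), sparse dark
speckle (immune cells), coarse patches (debris), concentric ring
motifs (glands), bright cell mosaics with thin dark boundaries
(adipose) and exactly constant tiles (background) — all tinted with an
H&E-like pink/purple palette with per-tile jitter.  Per-tile base
intensities are drawn from ranges that pairwise overlap across
families, reproducing the benchmark's bright-and-dark-samples design:
no pair of classes is separable by mean intensity alone (a property
test asserts this).  All randomness flows from explicit seeds; per-tile
seeds derive from (master seed, class, index).

Default study sizes: 50 tiles/class at 150 px for the reference
cross-validation run, 6 tiles/class at 96 px for exercising the full
48-experiment grid (96 px is the smallest tile admitting the largest
Gabor kernel), and a 600 × 600 four-region mosaic with a 7 × 7 tile
grid for segmentation recovery, scored on tiles lying fully inside one
region.

What passing these tests shows: the descriptors measure what they
claim, the classifiers and CV plumbing are correct, and the
segmentation engine recovers ground truth when classes are genuinely
texture-separable.  What it does not show: performance on real H&E
tiles, whose within-class variability (staining, scale, tissue
heterogeneity) far exceeds the synthetic families' — the near-perfect
synthetic accuracies are a correctness check, not a difficulty
benchmark.  Published accuracies on the real tile collection are
reproducible only with that dataset via
`scripts/reproduce_published.py`, and then only approximately, because
the original experiments' SVM hyperparameters and standardization
placement are not fully specified.

## Known limitations

- Colour information is discarded after greyscale conversion; no
  stain normalization or colour deconvolution.
- Only the (8, 1) LBP configuration and a single GLCM level count are
  wired in (both are keywords, not alternative feature sets).
- Per-pixel score averaging over overlapping tiles is not performed:
  scores attach to tile grid positions, matching the tile-resolution
  probability-map design.
- Whole-slide formats (SVS/NDPI) are out of scope; inputs are plain
  raster files.
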