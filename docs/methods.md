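# Methods

This note records the model, the conventions the implementation
commits to where more than one reasonable choice exists, what the
synthetic generator does and does not emulate, and the problem sizes
the test suite and acceptance script run at.

## Preprocessing

Raw photographs (any resolution, 8-bit RGB) are denoised by convolving
each channel with a discrete Gaussian kernel, `G(x, y) ∝
exp(−(x²+y²)/2σ²)` renormalized to unit sum, default 5×5 with σ = 1.0 —
small enough to preserve lesion borders while suppressing sensor noise.
Border handling is edge-inclusive reflection, which avoids the dark
halo that zero padding produces at image borders. The smoothed image is
resampled to 224×224 by bilinear interpolation under the
half-pixel-center convention (output pixel *i* samples the input at
`(i + 0.5)·scale − 0.5`); a native 224×224 input passes through
unchanged. All arithmetic stays in float; quantization to 8 bits
happens only on file export, so no rounding error precedes feature
extraction. Single-channel inputs are replicated to three channels with
a warning rather than rejected.

## Feature extraction conventions

**Color (96-d).** HSV with H ∈ [0, 360), S, V ∈ [0, 1] and 32
equal-width bins per channel. Libraries disagree on 8-bit HSV ranges
(e.g. H ∈ [0, 180) in some stacks), so the package defines these
canonical continuous ranges and uses them everywhere. Bins are
half-open with the last bin closed, so counts always partition the
50,176 pixels; zero-saturation pixels have undefined hue and are
assigned H = 0. Each 32-bin block is L2-normalized with ε = 1e−8, which
makes the descriptor invariant to overall brightness scaling of the
histogram mass.

**Texture (13-d).** Gray levels come from the luminance combination
0.299 R + 0.587 G + 0.114 B rounded to integers; the gray-level count G
defaults to 256 (no requantization) with a knob for coarser
quantization (8–64 is common practice) for sensitivity checks. The
co-occurrence matrix at distance 1 is accumulated symmetrically (each
ordered pair counted both ways), making P = Pᵀ. The 13 Haralick
statistics use base-2 logarithms throughout (entropies in bits) with
0·log 0 := 0; the same base is used inside the information measures of
correlation so IMC1/IMC2 stay internally coherent, and the IMC2
argument is clamped at zero before the square root. Degenerate
denominators return 0 — correlation when σx·σy = 0 and IMC1 when
max(HX, HY) = 0 — so constant images map to finite features. The
variance descriptor is the classic probability-weighted form
Σ (i − μx)² P(i, j). Sum/difference marginals are indexed by i + j ∈
[0, 2G−2] and |i − j| ∈ [0, G−1] with 0-based gray levels; this offset
convention affects only the sum-average location, not any
classification-relevant structure, and the test oracles mirror it. The
13-vector is the unweighted mean over the four directions; note that
the diagonal directions are labelled by the mathematical convention
(45° = up-right). Image-convention libraries label the same offsets
45°/135° in the opposite order, which leaves the direction *set* — and
hence the average — identical.

**Shape (7-d).** Moments are computed on the grayscale intensity image
directly — no binarization or segmentation — so the invariants reflect
the full intensity mass distribution, including internal texture, not
only the outline. Coordinates are x = column, y = row, 0-based. The
seven classic Hu polynomials are evaluated on normalized central
moments and compressed to a signed log scale with ε = 1e−10;
sign(0) := 0 maps exact zeros to 0 rather than ±10 (continuity at the
origin is impossible, so determinism is chosen). Under reflection the
first six invariants are preserved and the seventh flips sign, which
the suite uses as a structural check.

**Metadata (12-d).** Fixed order [age_z, gender, d1_z, d2_z, smoke,
drink, itch, grew, hurt, changed, bleed, elevation]. Continuous fields
are z-scored as (x − μ)/(σ + ε) with population σ and ε = 1e−8 fitted
on the training partition only; gender encodes Male = 1, Female = 0;
flags encode 1/0. Real clinical tables contain gaps, so the default
policy imputes missing continuous values with the train median (then
z-scores) and missing flags with 0, counting every imputation; a strict
mode rejects incomplete records instead. Tree ensembles are insensitive
to feature order and monotone scaling, so the fixed ordering matters
only for reproducibility of saved models.

**Fusion.** Plain concatenation [color | texture | shape | meta] with
block boundaries at 96/109/116; no rescaling at fusion, since each
block carries its own normalization and the downstream learners are
trees.

## Splitting and augmentation

The split is computed patient-level *before* any augmentation: each
patient is stratified by their most frequent class and patients are
assigned greedily per class until the test side approaches the target
fraction of that class's images, keeping patient-disjointness exact. A
class contributed by a single patient goes wholly to train with a
warning. Augmentation then expands each training class to a common
target (2500 per class balances the six clinical class counts to
15,000): replicas cycle uniformly over their class's parents, and every
replica draws its transform parameters from a private RNG stream keyed
by (seed, parent id, replica index), so regeneration is bit-identical
and independent of processing order. The transform order is fixed —
horizontal flip (p 0.5), vertical flip (p 0.5), rotation U[−30°, 30°],
brightness U[0.8, 1.2] clamped to [0, 255], affine jitter (p 0.5,
translation ≤ 10%, scale U[0.9, 1.1]) — because a reproducible
composition requires committing to one order; borders exposed by
rotation/affine are reflection-filled to match preprocessing. The test
side only ever contains genuine images, and an exhaustive scan
(`check_no_leakage`) asserts the invariants after pipeline runs.

## Ensemble

Three boosters are trained independently on identical data with the
common setting 500 iterations / depth 6 / learning rate 0.03: XGBoost
(regularized second-order objective), LightGBM (leaf-wise growth,
GOSS/EFB) and scikit-learn's `HistGradientBoostingClassifier`
(histogram-binned gradient boosting, trained without early stopping so
the iteration budget is honored). Remaining hyperparameters stay at
library defaults and are recorded in the saved model manifest. All
members run single-threaded for bit-reproducibility. The default
combiner averages the three class-probability distributions and takes
the argmax (soft voting); a hard majority-vote mode is available behind
a flag. Exact ties break to the lowest label index and are logged.
Gain-based feature importances are normalized per member and averaged
over the members that expose gain statistics (XGBoost, LightGBM).

## Metrics

All rates derive from per-class one-vs-rest counts of the confusion
matrix; macro variants are unweighted class means, F1 is macro-F1.
Cohen's κ uses marginal-product chance agreement; MCC is the Gorodkin
multiclass generalization; AUC is macro one-vs-rest, computed only when
probability scores are available (reported as absent, not 0,
otherwise), with subset probabilities renormalized when the evaluation
set lacks some classes. A class never predicted gets precision 0 with a
warning. Confidence intervals are percentile bootstrap (default B =
1000, level 95%) over resampled prediction/label pairs, seeded.

## Synthetic generator

Each class recipe controls exactly the channels the extractors measure:
a hue/saturation/value range for the blob fill, a spatially-correlated
noise amplitude and correlation length (texture roughness), an
eccentricity range and radial-harmonic border perturbation (shape), and
metadata priors (age and diameter distributions, symptom
probabilities). Images are a skin-toned background plus one elliptical
blob with a feathered, perturbed border. A single separability knob
interpolates class parameter ranges between disjoint (1.0) and heavily
overlapping; image and metadata separability can differ, which supports
the ablation probe where informative records rescue ambiguous images.
Patients own one to three lesions so the patient-level split is
exercised; everything regenerates bit-identically from the seed.

The generator makes no attempt at clinical realism: no hair, rulers,
ink markings, specular highlights, perspective, or multi-lesion frames,
and class-conditional structure is by construction aligned with the
feature blocks. Passing end-to-end tests therefore demonstrates that
the pipeline recovers class signal that its descriptors can express —
not that it reaches any particular accuracy on real clinical data.

## Problem sizes and numerical tolerances

The suite runs at desk scale: oracle equivalence on 100 random ≤16×16
images (tolerance 1e−9 against literal-formula brute force), invariance
checks at 1e−6 relative (discretization-limited checks at 1–2%), the
headline recovery benchmark at 100 lesions per class / separability 1.0
/ 500 iterations, the separability-monotonicity check at 30 lesions per
class and 120 iterations averaged over three seeds, and the
metadata-rescue probe at 40 lesions per class. These sizes were chosen
so the full suite completes in a few minutes on one CPU while keeping
every statistical assertion comfortably clear of its noise floor.

## Known limitations

* Histograms and moments are global over the frame; there is no lesion
  segmentation, so background composition leaks into all three visual
  blocks.
* Hu moments on intensity images mix contour and internal-texture
  information; they are not pure border descriptors.
* The greedy patient-level split approximates stratification; with few
  patients per class the test fraction can deviate by several images.
* The bootstrap is percentile, not BCa; intervals can be slightly
  anti-conservative at small n.
* Ensemble weights are fixed and equal; no hyperparameter search is
  performed beyond the stated common configuration.
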