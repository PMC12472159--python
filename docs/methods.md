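# Methods

## The interpretability question and the pipeline

A DR grader assigns one of five ICDR severity grades to a fundus
photograph. Clinicians grade by finding lesions: microaneurysms alone
mean mild DR (grade 1); exudates and hemorrhages appear from moderate
DR; more than 20 hemorrhages in each of the four quadrants (without
proliferative signs) marks severe DR (grade 3); neovascularization
marks proliferative DR (grade 4). The pipeline asks whether a
classifier's saliency maps land on those same structures.

The per-image procedure is: attribution map → bilinear resize to the
image grid → min–max normalization to [0,1] → binarization at a
percentile of the map's own pixel values → pixel-wise AND with each
lesion/landmark mask → binary "hit" per (image, method, lesion type).
Hits are aggregated per (grade, prediction-correctness, lesion) and
compared against manual judgments with Cohen's kappa.

## Attribution

**Target class.** Always the predicted class (ties to the lowest
index), because the question is what drove the decision actually made;
the true grade enters only through the correctness stratification.

**Pre-softmax scores.** Both methods differentiate the pre-softmax
class score. Softmax saturates (gradients vanish when one class
dominates) and couples classes; with pre-softmax scores, Grad-CAM is
invariant to adding constants to non-target logits, which the suite
tests explicitly.

**Grad-CAM.** Channel weights are the spatial mean of the class-score
gradient at the designated last convolutional layer; the weighted sum
over channels is rectified. The output lives on the conv grid and is
resized bilinearly (corner-aligned) to the image.

**Integrated Gradients.** Defaults: all-zero baseline (black is a
natural "no signal" reference for fundus photographs and makes results
reproducible without extra inputs), 64 trapezoid-rule steps (trapezoid
halves the completeness residual order compared to the left rule; 64
steps already gives ~1e-4 relative residual on the reference CNN, 256
gives ~5e-6), and per-channel attributions collapsed by the sum of
absolute values (`abs_sum`), since suppressive evidence is still
evidence of attention; `signed_sum` is available.

Adapters may expose `mean_path_gradient`, a fast path for the IG line
integral. The reference CNN implements it by exploiting linearity of
convolution: responses along the straight-line path interpolate
linearly between the endpoint responses, so the whole path costs two
convolution passes plus pointwise work instead of one backprop per
step. The generic per-step fallback remains, and a test asserts the
two paths agree to floating-point accuracy.

## Thresholding

The percentile is computed over all image pixels with the linear
interpolation convention (the numpy default, stated here for
bit-reproducibility); an optional FOV mask can restrict the population.
The ≥ comparison keeps ties, so the active fraction is at least
(100−p)/100, with equality on distinct-valued maps. Method defaults are
the 90th percentile for Grad-CAM (coarse maps) and the 97th for IG
(pixel-sharp maps). A constant heatmap is degenerate: it normalizes to
all zeros, every pixel satisfies 0 ≥ 0, the map is flagged and a
warning logged so reports can exclude it. This happens in practice for
grade-0 images whose predicted-class score has non-positive dependence
on every feature map (the ReLU clamps the whole map to zero).

## Masks and landmarks

Masks are binary, any positive pixel counts. Only the optic disc and
macula are post-processed — each exists exactly once per eye, so the
mask is reduced to its largest 8-connected component (8-connectivity is
the common blob-extraction default); size ties break to the component
containing the lexicographically smallest (row, col) pixel, making the
operation deterministic. Lesion masks are never cleaned: multiple
lesions are real. Patch tiling is row-major and exact; stitching
reconstructs the input bit-for-bit, and dimensions must divide by the
patch size (1120/224 → 25 tiles).

## Overlap scoring

The decision is "any overlap", not amount of overlap: Grad-CAM maps
are coarse and IG maps bleed past lesion boundaries, so graded overlap
against small lesions mostly measures map resolution, not attention.
IoU is still recorded per record using the Jaccard definition
(union denominator); when both sets are empty IoU is defined as 0 and
flagged. Counts per stratum come from unique image ids; inconsistent
duplicate records are a data error.

## Agreement

Kappa uses the standard two-rater binary formula. Conventions:

- stratum with no images → dash (`–`);
- chance agreement `p_e = 1` (both raters constant on the same
  category) → `N/A`, kappa undefined;
- exactly one rater constant → `p_o = p_e`, kappa exactly 0;
- both raters constant on *different* categories → `p_e = 0`, kappa 0.
  The verbal rule "undefined when labels have no variability" is
  ambiguous here; total systematic disagreement has a well-defined
  kappa by the formula, so it is reported, not suppressed.

The suite verifies the implementation against an exhaustive enumeration
of all 2×2 contingency tables with n ≤ 8 and against scikit-learn's
kappa where the latter is defined.

## Metrics

Multi-class F1, specificity and ROC-AUC are macro one-vs-rest over the
classes present (a common convention, stated because other averaging
choices change the numbers). AUC over classes lacking positives or
negatives is skipped; with fewer than two classes it is reported as
undefined. Score statistics use the probability of the true class for
correct predictions and of the (wrong) predicted class for incorrect
ones, with the sample standard deviation (n−1) and 0 for singleton
strata.

## Synthetic scenes

The generator emulates the geometry that matters to the pipeline, not
photorealism: a circular FOV on black, an orange-red background with
radial falloff and mild texture, a bright optic disc and darker macula
(both with smooth parabolic profiles — real landmark boundaries are
soft, and a hard synthetic edge would masquerade as lesion-scale
detail), low-contrast vessel arcs, and high-contrast lesions:
microaneurysms (dark dots, radius 3–4 px at the default 224 px image),
hard exudates (bright yellow blobs, 4–6 px), soft exudates (pale
blobs, 6–8 px), hemorrhages (dark red blobs, 5–7 px), and
neovascularization (thin bright random-walk tangles). Every shape is
rasterized into the image and its mask with the same coordinates, so
overlap ground truth is exact and mask false positives are impossible.
Hemorrhages are placed round-robin across quadrants so the per-quadrant
counts that decide grade 3 match the intent of the recipe. An optional
grey spot imitates dust on the camera lens; it appears in no mask and
serves as an attention confounder. Grades follow the ICDR rule stated
above; venous beading and IRMA are not rendered, so the severe grade
rests on the hemorrhage clause alone — a documented simplification.

What passing on these scenes does *not* show: robustness to the
blurred boundaries, annotator disagreement, segmentation-model false
positives/negatives, illumination artifacts and class imbalance of real
fundus data. The synthetic masks are exact by construction, so hit
rates here are upper bounds on what noisy segmentation masks would
give.

## The reference CNN

A fixed-weight convolutional scorer used as a deterministic,
hand-differentiable test subject: seven zero-mean centre–surround
template kernels (one per lesion/landmark appearance, on the colour
channel where that structure has most contrast) → softplus gate with
per-channel threshold and gain → global average pooling → linear
5-class head → softmax. The response thresholds sit between the
background/vessel response range and the template's target response,
so pooled features are nearly zero on lesion-free scenes; the head
operates on features centred at a frozen lesion-free reference, and
its weights were chosen by hand from the measured feature scales of
canonical scenes so that each canonical grade recipe classifies to its
grade with a margin of several standard deviations of the
seed-to-seed feature noise. All gradients (input-level, conv-level)
are written analytically and validated against finite differences in
the tests. The model is a desk-scale stand-in for a trained grader; it
is not intended to be competitive, only to make attribution behaviour
exactly checkable.

## Problem sizes and numerical choices

Default scenes are 224×224; tests use 96–128 px scenes where only
convergence behaviour matters. The acceptance-style suites use 20
scenes for IG completeness (residual bound 1e-3 at 256 steps) and 50
single-lesion scenes for the end-to-end hit-rate property (≥ 45/50 per
method; lesion types with empty masks can never be hit because the
masks contain no false positives). Heatmaps are stored as 32-bit float
TIFF, activation maps as 0/255 PNG, and all tables as CSV with kappa
rendered to 4 decimals. Bilinear resize is corner-aligned
(`scipy.ndimage.map_coordinates`, order 1), chosen so the closed-form
bilinear oracle in the tests is exact.

## Known limitations

- The ICDR severe-grade rule is reduced to its hemorrhage clause.
- Manual annotations enter only as a CSV of binary judgments; the
  package does not provide an annotation UI.
- The kappa N/A convention is formalized as `p_e = 1`; published
  tables using a looser verbal rule may mark more cells N/A.
- Percentile interpolation conventions differ between toolkits;
  results can shift by one pixel at ties under a different convention.
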