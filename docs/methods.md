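# Methods

This note documents the models, parameter choices and numerical conventions
behind `eastils`, and what the synthetic-data experiments do and do not show.

## Color model and stain estimation

Brightfield H&E follows Beer–Lambert absorption: per-channel optical density
`OD = -log10(max(I, 1) / I0)` is linear in stain concentration, so a pixel's
OD 3-vector is `c_h·v_h + c_e·v_e` for unit absorbance vectors `v_h`
(hematoxylin) and `v_e` (eosin). The background intensity `I0` defaults to
255 per channel (it can be measured from a background patch); the 1-unit
intensity floor inside the log caps OD at ~2.4 and keeps it finite.

Staining intensity drifts between slides, so stain vectors are re-estimated
per slide with a Macenko-style plane fit:

* exclude pixels with OD magnitude < 0.15 or any channel within 2 intensity
  units of `I0` (background);
* take the top two principal directions of the remaining (uncentered) OD
  cloud;
* within that plane, take the directions at the 1st and 99th percentile of
  the pixel angle distribution as the stain vectors;
* label the vector with the larger blue OD component hematoxylin (ties break
  to hematoxylin), and complete the basis with the normalized cross product.

A near-monochrome OD cloud (blank or single-stain tile) raises an estimation
failure; the pipeline then falls back to the conventional H&E vectors
(0.65, 0.70, 0.29) and (0.07, 0.99, 0.11). Deconvolution solves the 3×3
linear system per pixel and clamps negative concentrations to zero;
recomposition with the same profile reproduces the OD image to machine
precision before clamping.

The extreme-angle estimator assumes near-pure pixels of each stain exist.
On synthetic tiles the residual bias is ≈0.3° (hematoxylin) and ≈4.5°
(eosin, whose angle distribution is dominated by noisy stroma pixels); the
package's recovery requirement is 5° per stain, not bit-level agreement with
any particular GUI implementation.

## Nucleus detection

Detection runs on the hematoxylin concentration channel with these defaults
(all physical units):

| parameter | value |
| --- | --- |
| working pixel size | 0.5 µm |
| background radius (morphological opening) | 8 µm |
| median filter radius | 0 µm (skipped) |
| Gaussian sigma | 1.5 µm |
| OD threshold | 0.1 |
| nucleus area window | [10, 400] µm² |
| maximum background OD | 2 |
| cell expansion | 5 µm |

Pipeline: bilinear resample to the working pixel → (optional) median filter
→ Gaussian smooth → subtract the opened background → threshold → watershed.
Watershed markers are regional maxima of the smoothed foreground with a
minimum prominence of 0.05 OD (h-maxima; this suppresses noise ripples on
the flat tops of large nuclei), greedily merged when closer than 2 µm.

Object boundaries are then refined on a sharp version of the image (0.5 µm
smoothing only): each object keeps the pixels above half its peak
foreground OD. For a step edge the half-amplitude contour sits on the true
boundary, so measured areas track the underlying nuclei instead of their
smoothed halos — and nuclei genuinely below the 10 µm² floor stay below it.
The area window is enforced on the refined polygon area; a detection whose
local (opened) background OD exceeds 2 at its centroid is discarded as an
artifact.

Geometry conventions: µm coordinates, origin at the tile's top-left, pixel
centers at `(i + 0.5)·px`; polygons are unions of pixel squares, so polygon
area equals pixel count × pixel area exactly. Cell expansion partitions the
≤ 5 µm neighbourhood of the nuclei by nearest nucleus (Euclidean distance
transform), with a half-pixel allowance because distances are measured
between pixel centers; expansions of distinct cells never overlap.

## Features and classification

Per cell, in three compartments (nucleus, cytoplasm ring, whole cell):
mean/sd/min/max of hematoxylin and eosin OD; plus nucleus area, perimeter
(Crofton estimator, which has less rasterization bias than the chain-code
perimeter), circularity `4πA/P²` clamped to 1, eccentricity, maximum
caliper, and the cell/nucleus area ratio. Cells touching the image border
are flagged.

Each base feature is supplemented by neighbourhood-smoothed copies at 25 µm
and 50 µm: a Gaussian distance-weighted mean over cells within the radius,
weight `exp(-d² / (2(radius/2)²))`, including the cell itself. The kernel
scale (radius/2) is a package choice — only the radii are externally fixed —
and is isolated in one function.

The classifier is a feedforward network with eight hidden layers (width 64
by default, a package choice) trained for at most 100 iterations on z-scored
features, wrapped as a scikit-learn-compatible estimator. Probabilities are
reported in the canonical class order (tumor, lymphocyte, stromal, other);
exact ties resolve to the earliest class. Depth-8 training within 100
iterations is only stable with feature standardisation, hence the built-in
scaler whose parameters serialize with the model (JSON weights + schema).

Slide QC compares predicted labels against a reference labelling (ground
truth for synthetic tiles, pathologist review for real slides): a slide
fails when strictly more than 10% of its cells are misclassified; exactly
10% passes.

## Scoring

A cell belongs to the invasive-tumor region iff its nucleus centroid is
covered by the region (closed boundary), after subtracting exclusion
polygons (non-invasive lesions, normal structures). Areas are summed from
polygons clipped to the region, per class, and converted µm² → mm² in a
separate step so unit errors are independently testable. The default area
basis is the expanded cell polygon (the formula speaks of area occupied by
each cell type after expansion); a `nucleus` basis is available behind a
switch and is what synthetic-recovery experiments use, since planted ground
truth is defined by nucleus geometry. `easTILs% = 100 × lymphocyte / stromal`
with `stromal = region − tumor`; the score is undefined (an error) when
tumor fills the region.

## Synthetic data

Tiles: 150 × 150 µm at 0.4986 µm/pixel (a 20× scanner calibration) by
default. Nuclei are rasterized ellipses planted by rejection sampling
(≤ 1000 retries, error on overcrowding) with ≥ 4 µm clearance — the
"well-separated" regime under which detection is expected to be perfect. An
optional pair mode plants two lymphocytes at 6 µm center spacing, close
enough to merge after smoothing, to exercise watershed splitting. Default
morphologies (chosen for class separability; no quantitative morphology is
externally prescribed):

| class | geom. mean radius (µm) | eccentricity | hematoxylin OD |
| --- | --- | --- | --- |
| tumor | 6.0 ± 0.6 | 0.30 | 0.50 |
| lymphocyte | 2.6 ± 0.2 | 0.15 | 0.90 |
| stromal (fibroblast) | 4.0 ± 0.4 | 0.90 | 0.40 |
| other (apoptotic-body-like) | 2.2 ± 0.08 | 0.20 | 1.40 |

Stroma carries eosin OD 0.25 (0.05 under nuclei — nuclei displace the
eosinophilic matrix, which also gives the stain estimator near-pure pixels).
Gaussian noise (σ = 0.02 OD) is added in OD space before exponentiation so
stain recovery stays exactly invertible. Ground truth records every planted
polygon; per-class area sums are exact pixel counts × pixel area.

The generator does **not** emulate fixation artifacts, ink, folds, texture
within nuclei, chromatin patterns, or densely touching tissue; passing tests
therefore demonstrate correctness of the algorithms under their stated
assumptions, not clinical-grade performance on real slides.

Cohorts (defaults = the simulated study conditions): n = 113 patients, pCR
probability 33/113; easTILs% gamma-distributed with shape 2 and the scale
set so group medians are 36.1% (pCR) and 14.8% (residual disease); sTILs% is
`0.6 × easTILs% + N(0, 18²)` truncated to [0, 100], the noise scale chosen
so the easTILs/sTILs correlation is ≈ 0.6 at the default spread; arm
allocation 98/211 bevacizumab; EFS exponential (0.004/month events for pCR,
0.012 for residual disease) with uniform administrative censoring at 36–72
months; posttreatment easTILs% for residual disease is half the baseline
times lognormal noise. A logistic outcome mode (pCR ~ expit(a + b·easTILs%))
is available for calibration experiments.

## Statistics

Two-sided p-values throughout; 0.05 significance convention.

* Mann–Whitney: midrank ties; exact enumeration when both groups have
  n ≤ 8 and no ties, otherwise the tie-corrected normal approximation with
  continuity correction. Constant data across both groups → p = 1, flagged.
* Wilcoxon signed-rank: zero differences dropped; for ≤ 15 informative
  pairs the exact, tie-aware null distribution is built by convolution over
  sign flips (midranks doubled to integers), otherwise normal approximation.
* Chi-square (2×2): Pearson statistic without continuity correction by
  default (a flag enables Yates), df = 1.
* ROC/AUC: Mann–Whitney identity with ties counting ½; variance by DeLong
  structural components; Wald 95% CI clipped to [0, 1]. The paired DeLong
  test uses the component covariance; identical or rank-equivalent scores
  give p = 1 exactly.
* Kaplan–Meier / log-rank: product-limit curves per group (lifelines);
  log-rank via the standard hypergeometric variance; no events at all →
  p = 1 by convention; a single group yields curves without a test.
* Logistic regression: IRLS (GLM-binomial), tolerance 1e-8, ≤ 50
  iterations, patsy formulas; the marker×treatment interaction is the Wald
  test on the product term. Complete separation (detected via exploding
  fitted log-odds, or the IRLS failure itself) raises a dedicated error
  naming the worst covariate; rank-deficient designs are rejected.
* Control arms are pooled into one group before arm-level comparisons, as a
  cohort-prep transform separate from the tests.

## Problem sizes

The standard evaluation suite is 26 seeded tiles (6 train / 20 evaluation),
each 150 × 150 µm with 50 planted cells; the calibration experiments use
10,000 Mann–Whitney null replicates (n = 20 per group) and 100 logistic
fits at n = 300; cohort power uses 60 seeds at n = 113. These sizes make the
whole suite run in a few minutes on one CPU while keeping binomial error on
the monitored rates small relative to their acceptance margins.

## Known limitations

* Stain estimation needs both stains present; tiles dominated by one stain
  fall back to default vectors.
* The watershed marker rules (2 µm merge, 0.05 OD prominence) are package
  choices where only the outer parameter set is externally fixed; agreement
  with other implementations is at the level of ground-truth recovery, not
  bit-level.
* Smoothed-feature weights are Gaussian at scale radius/2; a uniform-weight
  alternative would change classifier inputs slightly.
* The classifier is retrained per experiment on synthetic labels; no
  pretrained weights ship with the package.
* easTILs% area basis (cell vs nucleus) changes the score's scale; compare
  scores only within one basis.
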