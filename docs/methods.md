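# Methods

This note documents the models, conventions and numerical choices
behind `nucrank`, in the spirit of a methods appendix: what is
computed, under which assumptions, and what the synthetic experiments
do and do not demonstrate.

## Segmentation assessment as ranked retrieval

The package treats object-level segmentation assessment as a ranking
problem rather than binary classification.  Each candidate
segmentation receives a posterior probability p̂ of being a
well-segmented single nucleus from a logistic regression on its
features; candidates are sorted on p̂.  Logistic regression is used
because its output is a calibrated posterior — unlike margin-based
classifiers it needs no recalibration layer, so probabilities are
comparable across training sets and directly usable as weights or
screening thresholds.  False positives (bad segmentations admitted to
position analysis) are the costly error; false negatives are cheap
because tissue provides surplus nuclei.

### Fractional targets

Reviewer labels live on the scale {0 = reject, 0.5 = maybe, 1 = good};
several reviewers' labels are averaged into a fractional target
y ∈ [0, 1].  The fit maximises the penalised mean Bernoulli likelihood

    (1/n) Σᵢ [ yᵢ ln p̂ᵢ + (1 − yᵢ) ln(1 − p̂ᵢ) ]  −  λ‖β‖²,

which is exactly the two-row expansion of each object into a positive
copy with weight y and a negative copy with weight 1 − y.  Using the
*mean* rather than the sum makes the estimate invariant to duplicating
the data, so λ has a fixed meaning across dataset sizes.  Features are
z-scored with training statistics stored in the model; optimisation is
L-BFGS with an analytic gradient.  The default ridge λ = 1e-4 exists
for numerical stability on separable data — with λ = 0 and separable
classes the optimum is at infinity, which the fit detects (coefficient
norm > 15 on z-scored features) and reports as an error advising
λ > 0.  Aggregation is the plain mean for any number of reviewers
(1–3 or more); the full range of attainable means is kept, not a fixed
set of values.

### Evaluation protocols

* **Leave-one-subject-out (LOSO).**  For each tissue core, the model
  is trained on all candidates of *other subjects* — never on the
  held-out subject's remaining cores — and scored on the core by ROC
  area.  This mirrors the clinical situation of scoring a new subject
  against a panel of previously annotated ones.  Holding out by
  subject while reporting per core reconciles subject-level
  independence with core-level resolution.
* **ROC.**  Computed by the tie-corrected Mann–Whitney rank
  formulation.  Fractional targets are binarised at 0.5 (≥ 0.5 is
  positive, so "maybe"-leaning objects count as positives); the
  threshold is exposed because no canonical binarisation of averaged
  reviewer labels exists.
* **Training-size curve.**  Random training subsets of dyadic sizes
  (default 8…1024) are drawn, the model fit, and ROC measured on the
  complement; repeated (500 repetitions by default, configurable) to
  estimate mean and variance per size.  Single-class subsets are
  redrawn a bounded number of times.

### Dataset quality

The quality of a core or subject is the mean posterior over its
candidates, (1/N) Σ p̂ᵢ — equivalently the area under the sorted,
domain-normalised posterior curve.  It estimates the yield of usable
nuclei: quality × candidate count ≈ number of usable nuclei, a
practical acquisition guide (keep imaging until the estimated yield
reaches the needed sample size).  The sum is computed with exact
(correctly rounded) summation so the score is literally invariant to
candidate order.

### Selection rules

Three screens convert a ranked list into the analysis population:
posterior threshold (default τ = 0.1 — low, because the posterior mass
concentrates near zero when most candidates are flawed), top-N, and
weight-passthrough (every spot later weighted by its object's
posterior).

## Features

Four families; names, formulas and constants are fixed in
`features.FeatureConfig`.  Where a feature has no single canonical
formulation, the convention chosen is listed here and config-exposed:

* **Perimeter** — 8-connected chain code, step weights 1 and √2.
* **Mean pairwise distance** — contour subsampled to ≤ 256 equally
  spaced trace points (bounds the O(n²) cost; relative error from
  subsampling is negligible at this density).
* **Polar histogram isotropy** — 36 angular bins of boundary-point
  counts about the centroid; statistic = coefficient of variation
  (0 = isotropic).
* **Severe corners** — turning angle over a 5-point contour window,
  severe if |angle| > 60°, non-maximum suppression within the window.
* **Box-counting dimension** — dyadic box sizes from 2 to
  min(side)/4, least-squares slope of log N(s) vs log(1/s); flagged
  missing when fewer than two sizes fit.
* **Erosion profile** — iterative erosion by the unit disk; statistic
  is the maximum over iterations of the number of connected components
  retaining ≥ 5 % of the original area.  A compact blob scores 1; a
  dumbbell (two bodies joined by a narrow neck — the typical
  under-segmentation) scores ≥ 2.
* **Elliptical Fourier count** — Kuhl–Giardina coefficients of the
  closed contour; the count is the smallest number of harmonics whose
  rasterised reconstruction differs from the mask by ≤ 10 % symmetric-
  difference area, capped at 20 (cap flagged).
* **Entropy** — 64-bin histogram of min–max-scaled in-mask
  intensities, log₂.
* **GLCM** — symmetric, distance 1, four orientations accumulated,
  32 in-mask quantisation levels, pairs restricted to in-mask pixels;
  contrast, correlation, energy, homogeneity.
* **Contextual family** — Delaunay graph on candidate centroids,
  edges pruned beyond 3× the median nucleus diameter (collinear
  layouts fall back to a principal-axis chain); betweenness is
  normalised.  The annulus for the intensity ratio is a 5-px dilation
  minus all candidate masks.  Contextual features are computed on
  request but **off by default**: they rank low in importance, cost
  whole-image I/O, and depend on segmentation density rather than the
  object itself.

Texture statistics reported are mean, range, entropy and the four GLCM
statistics (seven columns); the GLCM row of the feature taxonomy is a
family of statistics, and these four are the standard set.

Missing values (e.g. spot hull with < 3 spots, moment ellipse of a
degenerate object) are imputed as 0 with a companion binary flag
column, keeping the regression total and linear.

Feature importance is Breiman-style out-of-bag permutation importance
over a bootstrap ensemble of regression trees: per tree, the OOB
mean-squared error is compared before and after permuting each
feature.  Highly correlated feature pairs (|r| > 0.98) are flagged,
since permutation importance splits credit between duplicates.

## Gene centrality

For spot x in a nucleus with contour C and interior M:
edt(x) = min_C d(x, C); nedt(x) = 1 − edt(x)/max edt (0 at the
deepest interior point, 1 at the periphery); cedt(x) =
P(nedt(M) ≤ nedt(x)), the right-continuous empirical CDF over all mask
pixels.

Conventions, chosen to make the definitions literally true on the
discrete grid and exposed in the API:

* The EDT reference set is the set of **contour pixel centers** (mask
  pixels with a background 8-neighbour), not background pixels, so
  boundary pixels have edt exactly 0.  The field equals the
  brute-force all-pairs minimum exactly (the fast transform is exact,
  not approximate).
* Sub-pixel spot coordinates are evaluated by **bilinear
  interpolation** of the distance field, then transformed to
  nedt/cedt.  The field is defined on the whole bounding box so
  interpolation near the contour is well behaved; nedt is clipped to
  [0, 1].
* The cEDT population includes contour pixels.
* Distances are in pixels; µm conversion (default pitch 0.074 µm/px)
  applies to edt only — nedt and cedt are ratios.

**Discretisation.**  cEDT's uniformity (the probability-integral
transform, which is what makes it shape- and scale-invariant) is a
continuum property.  On a pixel grid the boundary contributes an atom
of mass ≈ perimeter/area at nedt = 1, so the KS distance of cEDT from
uniform is bounded below by ~2/r for a disk of radius r pixels.  The
uniformity and scale-invariance tests therefore use masks of radius
≳ 60–150 px — the regime of real nuclei at high magnification (a
7-µm nucleus at 0.074 µm/px has r ≈ 95) — where the discretisation
term is within the 0.02 tolerance.  Small synthetic nuclei (r ≈ 12,
used for pipeline speed) carry proportionally larger discretisation
error in cedt near the periphery; this affects absolute cedt values by
up to a few percent, not the ranking or the KS comparisons between
samples measured the same way.

**Repositioning comparison.**  Per-gene cEDT values are pooled over
the selected nuclei of a sample (optionally weighted by the source
object's posterior) and compared to a pooled control with the
two-sample KS test; a sample is *different* when p < α = 0.01.  The
asymptotic p-value is used above a combined n of 40, the exact
distribution below.  Test samples under ~100 spots trigger a low-power
warning.

**Stability.**  `synthgen.boundary_stability_experiment` measures the
same spots against reference and boundary-jittered outlines and
reports Pearson r and MAE for nedt and cedt plus an |error|-vs-radius
profile.  With ±2 px smooth jitter on radius-40 nuclei, r ≈ 0.97 for
both measures — the measures degrade gracefully with boundary error,
which is the property that makes automated screening viable at all.

## Synthetic cohort generator

The generator emulates what matters to this pipeline, not microscopy
optics:

* **Nuclei** are ellipses (aspect 1–1.8) modulated by low-order
  Fourier boundary perturbations (harmonics 2–5, amplitude set by
  `boundary_roughness` = 0.08 by default) — the simplest family that
  exercises the elliptical-Fourier, roughness and isotropy features.
* **Texture** is smoothed Gaussian noise scaled by `texture_contrast`
  inside the nucleus over a noisy background; it reproduces first- and
  second-order intensity statistics only, not chromatin structure.
* **Candidate masks** are derived from truth by a failure taxonomy:
  `good` (slight jitter, IoU ≥ 0.9 → label 1), `jitter` (moderate,
  IoU ∈ [0.7, 0.9) → 0.5), `merge` (bridged union of an adjacent
  pair → 0), `fragment` (straight cut through the nucleus, each piece
  → 0), `clip` (half-plane truncation; ≤ 25 % area removed → 0.5,
  more → 0), `debris` (small rough blob from no nucleus → 0).  The
  IoU cutoffs 0.9/0.7 are package conventions standing in for the
  qualitative reviewer criteria ("boundary is almost perfect" vs
  "minor errors"), which carry no numeric tolerance.  Boundary jitter
  is implemented as thresholding of signed distance plus smooth noise,
  with bisection on the amplitude to hit an IoU band.
* **Default mixture** (jitter 0.14, merge 0.22, fragment 0.20, clip
  0.13, debris 0.15, good 0.16) reproduces the regime where ~84 % of
  candidates are rejects — the situation the ranking exists for.
* **Spots** are placed so their nEDT values follow Beta(a, b)
  (default Beta(2, 2), mid-radial) by inverse-CDF over the sorted
  pixel nEDT population — exact at pixel resolution and free of
  rejection-sampling pathologies in thin shapes.  Optional sub-pixel
  jitter stays below 0.5 px so mask membership is unchanged.
* **Scale.**  Default images are 256 px with radius-12 nuclei and a
  4 × 2 × 2 subject/core/image tree (~200 candidates) — large enough
  for stable fits and LOSO evaluation while keeping the full test
  suite and the acceptance script fast.  `separable_spec()` builds a
  2-subject, 400-slot cohort of clean nuclei vs debris whose feature
  clusters are disjoint; it verifies that the retrieval machinery is
  lossless when the problem is trivially separable (every LOSO fold
  ROC = 1.0).

What passing on synthetic data shows — and does not.  The generator
demonstrates internal correctness: calibrated posteriors, leak-free
cross-validation, exact distance fields, invariant cEDT, a correctly
sized KS test.  It does not certify performance on real tissue, where
texture, staining variability and failure modes are richer than the
taxonomy modelled here; retraining on annotated candidates from the
actual segmentation algorithm is assumed, as the features that matter
depend on how a given segmenter fails.

## Degenerate inputs and tie-breaking

* Candidates of area < 9 px are flagged degenerate; inexpressible
  features are imputed 0 + flag.
* A label mask region splitting into several 8-connected components
  becomes several candidates with suffixed ids.
* Ranking ties are broken lexicographically by object id —
  reproducibility over arbitrariness.
* Spot membership uses the nearest-integer pixel; a spot in no mask is
  retained unassigned, a spot outside the image is dropped with a
  warning.
* An empty scope (quality), empty distribution (comparison), single
  class (ROC) and constant target (fit) raise descriptive errors
  rather than returning sentinels.

## Known limitations

* 2-D only: sectioning/projection bias is assumed to average out over
  unoriented nuclei; no 3-D centrality.
* The generator's debris is textureless-ish and its merges are
  geometric unions; real confounders (out-of-focus nuclei, stain
  gradients) are not modelled.
* Contextual features assume the candidate set is the image's nucleus
  population; with sparse candidates the neighbourhood graph is
  uninformative.
* The cEDT discretisation bias near the periphery (above) is inherent
  to pixel populations and shrinks as 1/r.
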