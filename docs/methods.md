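# Methods

`histomorph` implements a quantitative histopathology pipeline for H&E
tiles of solid tumors (designed around gastric adenocarcinoma):
nucleus segmentation and morphometry, aggregation to a canonical
150-dimensional patient feature vector, mutation–morphology association
testing, a cross-validated lasso-Cox prognostic risk index, and
image-feature–expression integration. This note records the models, the
parameter choices that matter, and the places where the design was
genuinely open.

## Stain normalization

Color variation between scanners/sites is reduced by working in optical
density, `OD = -log10(I/255)`. Pixels with summed OD below 0.15 are
treated as glass/background. The two dominant stain vectors are
estimated Macenko-style: SVD of the tissue-pixel OD cloud gives the
dominant plane; the 1st/99th percentile of the in-plane angle give the
extreme (pure-stain) directions; the vector with the larger red-channel
absorption is labeled hematoxylin. Per-pixel concentrations come from a
least-squares projection clipped at zero; they are rescaled by the ratio
of the reference profile's 99th-percentile concentrations to the
source's, and the image is rebuilt with the reference stain matrix
**plus the off-model OD residual**. Keeping the residual means structure
outside the two-stain subspace survives, and the map is an exact
identity when an image is normalized to its own profile. A tile with no
tissue pixels is returned unchanged with a warning flag. This is a
pragmatic rank-preserving normalization, not a replication of any
specific published method; the pipeline only needs it as preprocessing.

## Nucleus segmentation

Hierarchical multilevel thresholding on the hematoxylin concentration
image:

1. Otsu threshold isolates candidate foreground.
2. A second Otsu *within* the foreground splits dim (cytoplasm-like)
   from dark (nucleus) pixels — but only when the foreground is
   genuinely bimodal. Bimodality is judged by Ashman's
   D = |μ₁−μ₂|/√((σ₁²+σ₂²)/2) of the two classes; an Otsu split of
   unimodal Gaussian data already yields D ≈ 2.7, so the default
   threshold is 3.5. The same guard applied at level 1 makes a blank
   noisy tile return zero nuclei instead of thresholded noise.
3. Holes are filled; touching blobs are split by a watershed seeded at
   local maxima of the Gaussian-smoothed (σ = 2 px) Euclidean distance
   transform, with a minimum seed separation of 7 px. Smoothing the
   ridge keeps elongated single nuclei from being cut in two.
4. Regions under 30 px² (≈ 7.5 µm² at 0.5 µm/px) are discarded.

Detections with area strictly above the per-image 95th percentile
(nearest-rank) are removed as false detections — tissue folds and
similar artifacts produce implausibly large "nuclei". Whether this
percentile should come from one reference image or from each image was
ambiguous in the source protocol; it is computed per image here (adapts
to staining variation) and the percentile is a parameter.

## Cell-level features

Ten features per nucleus: area (px²); major and minor axis lengths of
the ellipse with the region's second central moments (a degenerate
region has its minor axis clamped to 1 px and is flagged); their ratio;
mean R, G, B intensities over the nucleus pixels; and the mean, max, and
min Euclidean distance to the nucleus's neighbors in the Delaunay
triangulation of nucleus centroids. Two nuclei are joined by a single
edge; collinear centroid sets, where triangulation is undefined, are
connected as a path in coordinate order; other Qhull failures get one
retry with a deterministic 1e-6 px jitter. Isolated nodes get missing
distance features and are excluded from distance-feature aggregation
only. Distances are in pixels unless a µm/px scale is supplied, in which
case all length features scale accordingly (mixing magnifications
without declaring a scale silently mixes units — hence explicit).
Boundary (long hull) edges are not pruned by default; a maximum
edge-length option exists.

## Patient-level aggregation

All slides of a patient are pooled into one cell table. For each of the
10 cell-level features: a 10-bin histogram of **proportions** plus five
statistics — mean, population SD, moment skewness g₁ = m₃/m₂^1.5,
non-excess kurtosis m₄/m₂², and Shannon entropy of the normalized bin
proportions (natural log, 0·ln 0 ≡ 0) — computed on the raw, unbinned
values. That is 15 per cell-level feature, 150 total, named
`area_bin1…area_bin10, area_mean, area_std, area_skewness,
area_kurtosis, area_entropy`, etc.

Histogram comparability across patients requires shared bins. How the
shared bins should be derived was an open design point; here they are 10
equal-width bins spanning the nearest-rank [P1, P99] of the reference
cohort's pooled values (the percentile clamp keeps outliers from
stretching the bins), serialized as JSON and reused bit-exactly for any
later cohort. Values below the first edge count in bin 1 and above the
last edge in bin 10. Constant pooled values are a degenerate range and
an error.

## Mutation–morphology association

Genes mutated in strictly more than 15% of patients are tested: each
gene × each of the 150 features with a two-sided Mann-Whitney U test
(exact by enumeration for combined n ≤ 12 without ties, otherwise normal
approximation with tie and continuity corrections; two identical
constant samples give p = 1). Fold change is median(mutated) /
median(non-mutated); a zero wild-type median gives a missing value, not
infinity. Benjamini-Hochberg q-values are computed over the full
gene × feature family by default (the family definition was unstated in
the source protocol; a per-gene mode is available). Significance is
q < 0.05. Groups with fewer than 2 patients are untestable and excluded
from the FDR family.

## Prognostic model

Per leave-one-out fold, using the training set only:

1. **Screening**: each feature is dichotomized at its training median
   (ties to the "≥ median" group) and tested with the two-group log-rank
   test; features with p < 0.05 are retained, uncorrected — this is
   deliberate trend-keeping screening, not inference.
2. **Lasso-Cox**: retained features are z-scored by training statistics
   (unstandardized L1 Cox would be scale-dependent across features with
   wildly different units); a 30-point regularization path is fitted
   (scikit-survival's coxnet, the same algorithm as R glmnet), and λ is
   chosen by 10-fold cross-validated partial log-likelihood using the
   Verweij–van Houwelingen contribution ll(train) − ll(train−fold), at
   the maximum (= minimum deviance). Ties prefer the stronger penalty; a
   "1-SE" rule is available behind `lambda_rule="1se"`. The inner-CV
   partition uses a fixed, configurable seed. A fold whose filter
   retains nothing emits an empty model and risk 0 for its held-out
   patient; a single retained feature is fitted normally.
3. The held-out patient's **risk index** is their training-standardized
   features dotted with the fold's coefficients. After all n folds,
   patients are split at the median risk index (ties to low-risk; all
   indices identical is a degenerate-distribution error), and the split
   is assessed with the log-rank test and Kaplan-Meier curves.
   Univariable/multivariable Cox models (lifelines) compare the risk
   group against dichotomized clinical factors with declared reference
   groups. Patients with non-positive follow-up are dropped with a
   warning (they break the partial likelihood).

Selection robustness is summarized per feature as the count of folds
with a nonzero coefficient and the mean coefficient **over the selecting
folds only** (an averaging convention; recorded in the output schema).

The two-group log-rank statistic (O₁−E₁)²/V with the hypergeometric
variance term is implemented directly and vectorized across features,
which makes the per-fold screening of 150 features cost milliseconds;
lifelines is the independent oracle for it in the test suite, and R
`cv.glmnet` was used during development as a cross-check of the λ
selection.

### Known limitation: in-cohort evaluation of pre-validated risk is anti-conservative

The final log-rank test of the median split is performed on the same
cohort the fold models were cross-fitted on. Although every fold is
strictly leak-free (verified: deleting the held-out row and refitting
reproduces the fold model bit-for-bit), the *evaluation* is not: under a
global null, the screening retains ~7 features per fold *because* they
correlate with training survival, the λ-min rule keeps most of them, and
fold models share n−2 patients, so the split aligns with the cohort's
survival noise. In simulation (50 null cohorts, n = 100) the split
reaches p < 0.05 in ~32% of cohorts with the default λ-min rule — the
familiar anti-conservativeness of significance-testing pre-validated
predictors — while the same splits tested against independently
regenerated survival are calibrated, and the 1-SE rule is conservative
(0/50). Cohort-level p-values from this protocol should therefore be
read as descriptive; a confirmatory p-value needs an external cohort or
a permutation reference. The screening filter itself and the association
tests are well calibrated (type-I ≈ 5% at nominal 5%).

## Synthetic data

The generators define the conditions under which the pipeline is
tested; they emulate structure, not appearance.

* **Tiles**: filled ellipses with lognormal areas (default mean 200 px²,
  SD 60 — nuclei of roughly 8 µm diameter at 0.5 µm/px) and lognormal
  aspect ratios clipped to ≥ 1 (default mean 1.5), uniformly random
  orientation, placed by hard-core rejection sampling (centroid
  separation default 25 px; overlap-free by construction; 10,000
  attempts per nucleus before an "overcrowded tile" error). Dark
  purple nuclei on a pale pink background with Gaussian pixel noise
  (SD 4). Ground truth: instance mask and per-nucleus table. No
  photorealistic texture, no nucleus clumping, no batch effects — so
  segmentation results here bound the easy case, not real H&E.
* **Cohorts**: the 150 patient-level features are independent unit-SD
  Gaussians around a positive baseline of 10 (positive so median-ratio
  fold changes are well-defined). Mutation labels are Bernoulli;
  mutated patients get the affected feature shifted by effect-size ×
  pooled SD. Survival is exponential with rate
  `baseline_hazard · exp(Σ β·z)` on z-scored post-shift features
  (default baseline 0.02/month, so median null survival ≈ 35 months),
  censored by an independent exponential clock (default 0.015/month,
  yielding ≈ 55% observed deaths) — months to match clinical follow-up
  conventions. Because features are drawn independently, these cohorts
  do not exercise feature correlation; lasso behavior under strong
  collinearity is covered only by a dedicated duplicated-column test.
* **Expression**: a driven gene is ρ·z(feature) + √(1−ρ²)·noise with
  ρ = 2 sin(π·s/6), the Pearson value whose bivariate-normal Spearman
  correlation equals the target s; s = ±1 gives a noise-free monotone
  transform and Spearman exactly ±1. Undriven genes are independent
  noise.

All generators are bit-reproducible given their seed.

## Expression integration

Spearman correlation (average ranks, pairwise-complete over missing
values) between a feature and every gene over the shared patients (≥ 10
required); genes with |ρ| ≥ 0.3 ranked by |ρ| (ties alphabetical),
capped at 100. If fewer than 10 qualify, enrichment is skipped and
flagged (the cutoff of 10 is this package's choice; it is
configurable). Over-representation of the selected genes in
user-supplied GMT gene sets is tested with a one-sided hypergeometric
test against a universe defaulting to all genes in the expression matrix
(the same sampling frame as the correlation), BH-adjusted across sets.
The boundary is inclusive (|ρ| ≥ 0.3) with a strict-inequality flag,
since both conventions appear in common usage.

## Problem sizes in tests and the acceptance script

Simulation studies use n = 200 null cohorts for calibration, n = 100
for the LOOCV null audit, n = 300 with |β| = 0.8 on three features for
recovery, a 1.5-pooled-SD shift at 50% frequency for association power,
and HR = 2 for Cox coverage. Replicate counts are 100 seeds for the
cheap studies and 25–50 for the LOOCV-based ones, which keeps the whole
acceptance run around ten minutes on one CPU at the cost of wider
Monte-Carlo error on those two rates.
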