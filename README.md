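# histomorph

Quantitative histopathology for H&E tumor tiles: nucleus morphometry,
mutation–morphology association, and a cross-validated prognostic risk
index. Built for computational-pathology analyses of the kind run on
TCGA gastric adenocarcinoma cohorts — RGB tiles plus per-patient
clinical, gene-level somatic mutation, and expression tables — and for
anyone who wants the whole chain (segmentation → features → cohort
statistics) as tested, scriptable Python rather than a one-off
pipeline.

## What it computes

**Features.** Tiles are stain-normalized in optical-density space,
nuclei are segmented by hierarchical Otsu thresholding with watershed
splitting, and detections above the per-image 95th area percentile are
dropped as artifacts (tissue folds). Each nucleus yields 10 cell-level
features — `area, major, minor, ratio, rMean, gMean, bMean` and the
mean/max/min distance to its Delaunay-graph neighbors. Per patient,
every cell-level feature is summarized over all pooled slides into a
10-bin histogram of proportions (cohort-shared bins) plus mean, SD,
skewness, kurtosis, and entropy: the canonical 150-feature vector
(`area_bin1 … distMin_entropy`).

**Association.** For each gene mutated in >15% of patients, each
feature is compared between mutated and wild-type patients with a
two-sided Mann-Whitney U test; fold change is the median ratio; FDR is
controlled with Benjamini-Hochberg q-values over the gene × feature
family.

**Prognosis.** A leave-one-out cross-validated lasso-Cox risk index:
per fold, features are screened by median-dichotomized log-rank tests
(p < 0.05, uncorrected), z-scored, and fitted with an L1-penalized Cox
model whose penalty is chosen by 10-fold cross-validated partial
likelihood — all strictly inside the training set. The held-out risk
index is x·β̂; the cohort is median-split into low/high-risk groups and
assessed with log-rank, Kaplan-Meier, and uni/multivariable Cox models
against clinical factors.

**Integration.** Frequently selected prognostic features are correlated
(Spearman) with gene expression; the top genes (|ρ| ≥ 0.3, ≤ 100) are
tested for hypergeometric over-representation in user-supplied GMT gene
sets.

A synthetic-data module generates ground-truthed tiles (elliptical
nuclei, hard-core placement), cohorts with planted mutation shifts and
proportional-hazards signal, and feature-driven expression — the basis
of the test suite and the simulation studies.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (inputs under `scratch/demo/`, tables under `results/`):

```sh
python analysis/01_simulate.py            # tiles + cohort with planted truth
python analysis/02_extract_features.py    # segment, measure, aggregate
python analysis/03_mutation_association.py
python analysis/04_prognostic_model.py
python analysis/05_expression_enrichment.py
python analysis/06_simulation_studies.py  # calibration & power rates
```

On the demo cohort (200 patients; a TP53-like mutation shifting
`area_mean` by 1.5 pooled SD; log-hazard β = ±0.8 planted on
`area_bin6`, `minor_mean`, `bMean_bin10`) the scripts print:

```
segmentation: 1142/1200 ground-truth nuclei matched, 0 spurious
feature matrix: 20 patients x 150 features

150 gene x feature tests, 1 significant at q < 0.05
gene   feature            p            q  fold_change
TP53 area_mean 1.096109e-21 1.644163e-19     1.166041

most frequently selected features:
    feature  count  n_folds  frequency  mean_coefficient
  area_bin6    200      200        1.0          0.839699
bMean_bin10    200      200        1.0          0.635307
 ...
risk-group stratification: log-rank chi2 = 76.14, p = 2.64e-18

area_bin6: 9 genes at |rho| >= 0.3; top set DRIVEN_SET (overlap 9, q=2.12e-13)
```

Reading: the association stage finds exactly the planted gene–feature
pair (a 17% median increase in mutant patients); the LOOCV model selects
the three planted survival drivers in every fold with the right signs
and separates the risk groups decisively; and the expression stage
recovers the gene set planted on `area_bin6` while correctly skipping
features with too few correlated genes. The ~5% of ground-truth nuclei
not matched are the ones removed by the 95th-percentile size filter, by
design.

The same machinery is exposed as a CLI (`histomorph simulate | segment |
cellfeat | aggregate | assoc | prognosis | exprcorr | run`) for running
the pipeline on real tiles and tables; `histomorph run --config
pipeline.json --out out/` executes every stage with provenance tracking
and byte-identical re-runs.

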