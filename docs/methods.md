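# Methods

## Problem setting

Given a drug × protein matrix of continuous binding-affinity scores
(pKd-like or KIBA-like units) with an explicit observed mask, a
drug–drug chemical-structure similarity matrix and a protein–protein
sequence similarity matrix (both in [0, 1], unit diagonal), `dtarank`
predicts affinities under two cold-start scenarios: **S1** holds out
whole drugs (proteins act as ranking queries) and **S2** holds out whole
proteins (drugs act as queries). Similarity matrices are *inputs*: the
package does not compute fingerprints or alignments.

## Feature model

Every entity carries 22 self-associated statistics (SAF): five order
statistics of its similarity profile (mean, 50/75/85/95th percentiles,
self-similarity excluded), eleven statistics of its observed affinity
profile (mean, count, mode, 25/50/75th percentiles, five highest, five
lowest), and the affinity-row mean. Adjacent-associated features (AAF)
are the component-wise mean of the SAFs of the entity's neighbors under
one of two schemes:

- **threshold** — all entities whose similarity (or shared-partner
  count) with the target *strictly exceeds* a threshold, ordered by
  descending value with id tie-breaks;
- **top5exp** — the 5 most similar entities plus each of their own
  top 5, deduplicated before aggregation (aggregating duplicates would
  silently reweight them).

Sharing matrices count common binding partners after binarizing observed
affinities at an activity cutoff: pKd ≥ 7.0 (Kd ≤ 100 nM) by default,
12.1 being the customary choice on the KIBA scale. The diagonal stores
the entity's own partner count and is never used as a feature.

The default block grid builds, per side, one SAF block plus six AAF
blocks (similarity thresholds {0.3, 0.5, 0.7}, sharing thresholds
{1, 3}, top5exp), i.e. 2 × 22 × 7 = 308 columns. The grid is a
configuration knob; the column count is fully determined by it.

### Conventions for statistics

- Percentiles use linear interpolation between order statistics
  (NumPy's default, the "type 7" rule).
- The mode of a continuous profile is the most frequent value after
  rounding to 2 decimals; ties resolve to the smallest value.
- With fewer than five observed affinities, the top-5/low-5 slots repeat
  the last available order statistic.
- Entities with *no* training affinities (cold entities, by
  construction all test-side entities of the cold scenario) receive the
  global training-mean affinity in every affinity-derived statistic and
  count 0; their information enters through the AAF blocks.

### Leakage policy

All affinity-derived quantities — profile statistics, sharing matrices,
the cold-start fill — are computed from the training pairs' affinities
only. For each *training* pair, the pair's own label is additionally
masked before computing that row's profile statistics, so no row's
features ever see its own label. Held-out labels are carried through the
tables solely for evaluation; zeroing them changes no feature value
(asserted exactly in the test suite).

## Feature-set optimization

- **Variance threshold**: drops columns with training-row variance
  (ddof = 0) ≤ the threshold; the conventional sweep is
  linspace(0.01, 0.1, 5).
- **PCA**: z-scored on training statistics, full SVD, dimension fixed or
  chosen by the maximum-likelihood ('mle') criterion; fitted on training
  rows only.
- **Lasso**: alpha chosen by 5-fold cross-validated MSE on standardized
  training rows; features with non-zero coefficients are kept.
- **Boosted-tree select-from-model** (XGBoost / LightGBM): exhaustive
  grid search by 5-fold CV MSE (default grids: n_estimators
  {200, 400, 600, 800}, max_depth {3–6}, learning_rate {0.02–0.08}),
  refit at the best point, features scored by total gain, and those with
  importance ≥ the mean (configurable: median) of the *non-zero*
  importances retained. A CatBoost backend id is reserved and raises an
  explicit error because the catboost package is not a dependency.

Grid-search folds are seeded; every selector sees only training rows.

## Ranking model

MART (multiple additive regression trees) is realized as squared-error
gradient boosting over regression trees: a regression model whose
within-query ordering serves as the ranking — the appropriate reading
when the target is a continuous affinity and the evaluation is CI plus
MSE/rm². A pairwise (LambdaMART-style) objective is exposed as an option
on the XGBoost backend only, since LightGBM's lambdarank requires
integer relevance grades. Defaults: 400 trees, depth 4, learning rate
0.06 (mid-grid values). Fits are single-threaded and seeded; identical
inputs give bit-identical serialized models. LightGBM is the default
backend because its predictions and SHAP contributions are computed in
double precision, which keeps the SHAP identities below exact
tolerances; XGBoost (float32 prediction path) is selectable.

## Metrics

- **CI** — over all pairs (i, j) with yᵢ < yⱼ: 1 if sᵢ < sⱼ, 0.5 if
  sᵢ = sⱼ; implemented with a Fenwick tree in O(n log n), and proven
  equal (bit-for-bit) to the O(n²) definition on random vectors with
  ties. Undefined (error) when all labels tie.
- **MSE** — mean squared difference.
- **rm²** — r²·(1 − √(r² − r₀²)) with r² the squared Pearson correlation
  of labels on scores and r₀² = 1 − RSS₀/TSS for the least-squares fit
  of y on s through the origin (slope k = Σys / Σs²); r² − r₀² is
  clipped at 0 against floating-point jitter. rm² is not symmetric in
  its arguments; labels come first.
- Evaluation pools all pairs by default (the common benchmark practice);
  a per-query mode averages CI over queries with ≥ 2 distinct labels and
  reports the number skipped.

## SHAP ranking and incremental feature selection

Per-feature scores are the mean absolute TreeSHAP value over the
training rows, obtained from the backend's native contribution
predictor and verified on the fly against local accuracy
(Σφ + base = prediction, tolerance 1e-6; observed gaps are ~1e-14 with
the LightGBM backend). IFS retrains the model — same hyperparameters and
seed, no re-search — on nested top-k prefixes (k = 5, 10, …, full) and
evaluates each on the held-out rows. The *stable dimension* is the
smallest k whose CI and all later CIs stay within a tolerance
(default 0.005 CI) of the full-dimension CI; this tolerance is this
package's definition of "stable", chosen as roughly the run-to-run
jitter of CI at these sample sizes.

A brute-force Shapley oracle (exponential subset enumeration, ≤ 10
features) marginalizes absent features over an explicit background
sample: v(S) is the mean prediction with features in S taken from the
explained row and the rest from each background row. With the training
set as background this coincides exactly with path-dependent TreeSHAP on
depth-1 stump ensembles (the cover weights *are* the training counts),
which is the regime where the oracle cross-checks the backend; passing a
single mean row as background recovers plain mean-imputation.

## Synthetic data generator

The generator emulates the two shapes of public DTA benchmarks — a
small dense panel (Davis-like preset: 68 drugs × 442 proteins, fully
observed) and a large sparse screen (KIBA-like preset: 2111 drugs × 229
proteins, ~24.5% observed) — via a low-rank latent factor model:

  u = μ·e + N(0, s²I_r) per drug (likewise v per protein, e the unit
  ones-vector), affinity = base + scale·(u·v) + N(0, σ²),

with defaults r = 3, μ = 1.0, s = 0.5, base = 7.0, scale = 1.5,
σ = 0.3 — a pKd-like range of roughly 7 ± 2.5. Similarities are the
cosine of the latent factors mapped to [0, 1] by (x + 1)/2; missingness
is MCAR, with at least one observation kept per entity.

The nonzero latent center is deliberate: a zero-centered factor model is
a pure drug × protein interaction with no main effects, and *no*
per-entity aggregate statistic (which is what SAF/AAF are) could predict
it even in principle. Real affinity panels have strong main effects —
promiscuous kinases, broadly potent compounds — and the offset plants
exactly the structure the method's premise requires: entities with
aligned factors are similar *and* have correlated affinity rows
(verified on the standard draw: drug pairs with latent cosine > 0.95
average row correlation ≈ 0.85).

What the generator does **not** model: realistic marginal affinity
distributions (Davis' censoring spike at pKd 5), structured missingness
(KIBA's is anything but MCAR), assay noise heteroscedasticity, and
chemically meaningful similarity. Passing tests on this data show the
pipeline recovers planted neighborhood structure under cold-start — not
that it attains any particular benchmark number.

### Permutation control

The null control shuffles the observed *training* affinities before
feature extraction, reruns feature building and training, and scores
against the true held-out labels. Permuting labels only at the model
stage is not a valid null here, because the features themselves are
functions of the training labels and would still carry structure.

## Problem sizes and numerical choices

The standard study condition used by the tests and the acceptance script
is 60 drugs × 100 proteins (4800 train / 1200 test pairs at a 20%
cold-drug split), 308 feature columns, 400-tree models — each full
pipeline pass takes a few seconds on one CPU. Grid searches in tests and
the acceptance script use reduced grids (e.g. n_estimators {200, 400} ×
max_depth {3, 5}) around the default operating point; the full default
grids remain available through the API and CLI. Matrix symmetry is
enforced to 1e-9; model round-trips are exact because both backends
serialize to full-precision text.

## Known limitations

- The exact threshold grid that would reproduce any particular published
  feature dimensionality is not recoverable from matrix inputs alone;
  dimensionality is config-driven.
- AAF aggregation is a mean (optionally similarity-weighted); other
  reductions (concatenation, max) are not implemented.
- Cold entities whose neighbors are all cold themselves receive
  fill-value AAFs and are effectively unpredictable — inherent to
  similarity-only cold start.
- The CatBoost selection backend is a stub that reports its absence.
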