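# Methods

This note documents the models, conventions and design choices behind
`geoenrich`, in the spirit of a statistical software methods appendix. It
states no empirical number that the test suite or `scripts/acceptance.py`
does not itself compute.

## Geometry

All distances are great-circle distances on a sphere of mean radius
R = 6371.0088 km, matching the spherical model underlying the Web-Mercator
projection used by map tiles. The documented conversion constant is
111.195 km per degree of latitude (2πR/360 to the printed precision).

Bounding boxes serve as a prefilter for radius queries, so their one
non-negotiable property is that they never exclude a point within the query
radius. The latitude half-width is r/111.195 degrees. For longitude, the
common first-order rule Δlon = Δlat / cos(lat_center) slightly under-covers:
a ground circle's easternmost point lies poleward of its center's parallel,
so at high latitude the circle's longitude extremes poke past the box by up
to a few hundredths of a percent of r. We therefore use the secant of the box
edge latitude nearest the pole, which is strictly wider and provably
sufficient, at the cost of a box a few percent wider than the minimal one at
alpine latitudes. Boxes crossing a pole or the antimeridian are rejected
with an explicit error; the intended study regions never need them.

Radius membership is a closed ball (a record at distance exactly r counts),
and time windows are closed intervals; ties are always counted in.

## Land-use fractions

Tiles are stitched into a crop covering the bounding box, each pixel is
assigned to the first legend entry whose reference color matches within the
per-channel tolerance (first-match-wins makes overlapping tolerances
deterministic), and class fractions are weighted pixel counts inside the
region mask. In Web-Mercator the ground length of a pixel edge scales with
cos(latitude) in both axes, so ground area per pixel scales with
cos²(latitude); row weights use cos² by default (`weighting="cos"` and
`"none"` are available for comparison). The region is a circular mask of
the query radius by default; `region_shape="square"` uses the full crop,
which is what the exact-area oracle tests use because the spherical area of
a lat/lon-aligned rectangle has a closed form
(R²·Δλ·(sin φ₂ − sin φ₁)) while a geodesic circle's intersection with
painted rectangles does not.

Expected accuracy: at zoom 13 the remaining error against exact spherical
truth is dominated by pixel rasterisation of class boundaries and stays
well under one percentage point for kilometre-scale regions; the acceptance
suite verifies < 1 point at latitudes 0°, 47° and 60°.

## Climate and regional statistics

Climate grids are treated as already interpolated (5 km default spacing):
lookups return the nearest cell center's value with no further
interpolation, and NaN cells propagate. Temporal averages pool all grids of
one variable whose date falls in the civil day, month or year containing
the query date, skipping missing values and reporting how many days
contributed. Region resolution is polygon containment (boundary inclusive)
with a deterministic lexicographic tie-break on shared boundaries.
Regional values are attached verbatim; dividing by region area is an
explicit opt-in (`normalize_by_area`) because silent unit changes in
third-party statistics are a classic source of analysis artifacts.

## Alpha diversity

For one sample with taxon counts n_i, total N, richness R (taxa with
n_i > 0), p_i = n_i/N, singletons S₁ and doubletons S₂:

- Shannon entropy H′ = −Σ p_i ln p_i (natural log, in nats);
- Simpson diversity D = 1 − Σ n_i(n_i−1) / (N(N−1)), the probability that
  two individuals drawn without replacement differ in taxon;
- Simpson evenness E = (1/λ)/R with λ = Σ p_i², in (0, 1]. A published
  variant of this formula carries a leading minus sign, which would make
  evenness negative and unusable as a regression target; we return the
  positive value and keep the signed variant behind `eq3_literal=True`;
- bias-corrected Chao1, C = R + S₁(S₁−1)/(2(S₂+1)) ≥ R.

Samples with totals ≤ 1000 reads are discarded (strictly greater than
survives). Depth bias is removed by rarefaction: a multivariate
hypergeometric subsample (without replacement) of every retained sample to
a common depth — by default the smallest retained total, the largest depth
all samples share — with each index averaged over 10 seeded replicate
draws.

## Ensemble feature selection

The pipeline runs in fixed order: prefilter → correlation pruning →
ensemble importance → mean-weight cutoff.

*Prefilter.* A feature is dropped if it has any missing value, if its zero
fraction strictly exceeds 1/3 (enrichment outputs are extremely sparse and
mostly-zero columns carry no usable signal), or if it is constant.

*Correlation pruning.* Features are visited in descending |Spearman ρ| with
the target; each joins the first earlier representative with pairwise
|ρ| > 0.7, else becomes a representative. The representative of each group
is thus its most target-correlated ("most descriptive") member, and the
group map is preserved so a selected feature can be read as a stand-in for
its correlated set — in enrichment data whole families of features (the
same quantity at several radii, related statistics of one theme) are
near-duplicates.

*Importance ensemble.* K = 4 measures, each producing non-negative scores
normalised to sum to 1/K so the ensemble weight sums to 1 exactly:

1. |Pearson correlation| with the target;
2. |Spearman correlation| with the target;
3. permutation importance of a bagged-trees regressor (bootstrap forest,
   all features eligible per split, depth capped at 3 so the committee
   votes on main effects instead of memorising a few dozen instances);
   importance is the mean decrease in training R² when a feature column is
   shuffled, negatives clipped to zero. Features used in no split are
   skipped — their permutation importance is identically zero;
4. an L1 path: lasso on standardised features with the penalty chosen from
   a 10-point relative grid by 5-fold cross-validation, the support refit
   by least squares (relaxed lasso) and scored by |coefficient|, plus one
   iterated-screening pass — the refit residual is correlated against all
   features so a predictor masked by the selected set still receives mass.
   The two halves are normalised to 0.5 each.

A method returning all-zero scores contributes uniformly, keeping the
ensemble total at 1. The measure set is pluggable; a correlation-only
configuration (K = 2) is provided for resampling loops where fitting a
forest and a lasso path inside every fold of every permutation is
computationally out of reach.

*Cutoff.* Features whose ensemble weight strictly exceeds the mean weight
(= 1/F by construction) are selected; if all weights are equal everything
is kept.

A structural property of this design worth knowing: because the
model-based measures concentrate their mass on few features, a feature they
ignore needs roughly twice the mean correlation share to clear the
mean-weight bar. Weakly associated but genuine predictors therefore sit
near the selection boundary; the planted-recovery test in the acceptance
suite quantifies this under a demanding sparse regime (five independent
unit effects among 1,200 features at n = 40), where even an oracle least
squares fit on the true support occasionally leaves a planted feature
statistically undetectable.

## Evaluation and inference

Leave-one-out cross-validation repeats the entire selection pipeline on
every training fold; the held-out instance is predicted by a regressor
trained on that fold's selected features only. If the held-out row carries
missing values in selected columns (possible, since the training-fold
prefilter only sees training rows), they are imputed with training-fold
feature means — a leakage-free convention, as no held-out information
enters the fold. Shipped regressors: OLS,
ridge, k-nearest-neighbours, a single CART tree, bagged trees,
gradient-boosted trees, the fold-mean, and a zero-constant baseline; any
fit/predict factory can be registered. One master seed fans out
deterministically (via a seed sequence) to folds, the bootstrap, the
permutations, and model randomness.

Pooled R² is the squared Pearson correlation of the n held-out predictions
against the observations, which is bounded in [0, 1]; the coefficient of
determination is available separately. One caveat is documented rather than
hidden: under this scoring the fold-mean predictor is exactly
anti-correlated with the held-out values (its prediction is
(S − y_i)/(n−1)), so it scores near 1 despite having no skill. The
meaningful zero-skill baseline is the constant predictor, whose degenerate
prediction vector scores 0 by convention. This artifact is also why
significance comes from a permutation test rather than from comparing R²
to a nominal null level: the test reruns the full pipeline — per-fold
selection included — on B shuffled targets and reports p = t/B, where t
counts permuted scores ≥ the observed score (ties count; t = 0 is reported
as "< 1/B").

Bootstrap confidence intervals resample (prediction, observation) pairs
with replacement B = 1000 times and take the 2.5/97.5 percentiles of the
recomputed R²; degenerate resamples with a constant vector are redrawn and
counted in the log.

## Stability diagnostics

Each fold yields a ranked feature list (descending ensemble weight,
lexicographic tie-break); the top-k (default 50) lists of all fold pairs
are compared by Kendall τ-a on the induced rankings of their shared
features — integer pair counting, exact at the ±1 boundaries; with strict
ranks the tie-corrected τ-b coincides — and by Jaccard distance on the
sets. Fold lists under LOOCV share all but one training instance per pair,
so even a permuted (but fixed) target produces moderately stable lists;
the informative quantity is the *contrast* between a real-signal table and
its target-permuted twin, which the acceptance suite measures as a paired
20-seed comparison. The per-rank summary reports the mean weight at each
rank normalised to rank 1 and the relative frequency of the modal feature
name per rank, which decays toward noise with increasing rank.

## Synthetic fixtures

Every generator is a pure function of a spec and seed and emits
machine-readable ground truth that tests consume instead of re-deriving:

- *map tiles*: disjoint lat/lon rectangles of legend colors painted by
  pixel-center membership; truth is the exact spherical area of each
  rectangle clipped to the query box;
- *points*: uniform in a box with categorical labels and optional
  timestamps; truth by brute force at query time;
- *climate*: value(i, j, day) = base + a·i + b·day + noise, with the
  closed-form period mean recorded;
- *regions*: an n×n rectangular grid of polygons with a wide sparse
  statistics table and exact spherical cell areas;
- *communities*: per-sample lognormal abundances (σ = 1.5) normalised to
  probabilities, multinomially sampled at fixed depth; the generating
  probabilities and their analytic H′, D, E are returned as asymptotic
  truth;
- *feature tables*: planted features with unit effects on the target,
  correlated decoy blocks (latent loading 0.95, population within-block
  |ρ| ≈ 0.90 so the > 0.7 block contract also holds in sample), and
  independent noise. Zero-inflation is stratified — exactly round(rate·n)
  zeros per inflated feature — so a nominal 30% rate cannot stochastically
  cross the strict 1/3 prefilter cutoff; the target is built from the
  observed (post-inflation) planted values plus Gaussian noise, and
  missingness is applied only outside the planted set, since any missing
  value disqualifies a feature by contract.

The default "austria-like" preset mirrors the shape of a small alpine-lakes
campaign: 39 instances, roughly a thousand usable features after
filtering, radii of 1, 2 and 5 km, an August sampling date. What these
fixtures do *not* emulate: real spatial autocorrelation between nearby
lakes, heavy-tailed and discrete feature distributions of real regional
statistics, database version drift, or correlated missingness — so passing
tests demonstrate correctness of the machinery and calibrated behaviour
under the stated generative model, not performance on real survey data.

## Problem sizes used in tests and the acceptance script

Chosen as the package's standard verification sizes: geometry oracles use
10⁴ random containment trials and 20 radius queries against 10³ points;
land-use oracles run at zoom 13 over ~2 km regions; planted-feature
recovery uses 20 replicates of 40 × 1,200 tables with the full K = 4
ensemble; LOOCV/permutation checks use 36 × 100 tables (five planted
effects, σ = 0.3) with the correlation-only ensemble and ridge regression,
B = 100 for the signal case and B = 30 across 20 seeds for null
calibration; the stability contrast uses 24 × 240 tables with twenty
planted effects (σ = 0.5). The bootstrap runs at its default B = 1000.

## Known limitations

- Antimeridian- and pole-crossing queries are rejected, not handled.
- Nearest-cell climate lookup ignores grid convergence at high latitude
  (cell lattice is anchored at the grid origin's parallel).
- The permutation test is exchangeable-null only; it does not account for
  spatial autocorrelation between instances.
- Recovering *all* members of a weak effect set under the mean-weight
  cutoff is not guaranteed in the sparse wide-data regime (see the
  ensemble-selection section); reported feature lists should be read
  together with their correlation groups and stability diagnostics.
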