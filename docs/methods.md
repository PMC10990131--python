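# Methods

## The modelling problem

Commercial rice yields at county level respond to weather, to the genetic
composition of what is planted, and to their interaction. Variety acreage
reports say *what* was planted where; a genotyping panel says what alleles
each variety carries; weather and yield records complete the picture. The
pipeline links them in four stages: aggregation of genotypes to
county-year allele frequencies, feature engineering with PCA, a stacked
ensemble yield model, and composite-variety-group (CVG) backcasting and
forecasting under climate scenarios.

## Bag-of-alleles aggregation

For county-year rows, the allele frequency of marker *j* is
`c_j = Σ_i A_i m_ij` with `A_i` the acreage proportion of variety *i* and
`m_ij` its binary call. Decisions taken where the procedure is
underdetermined:

- **Coverage filter.** County-years with fewer than 80 % of grown
  varieties genotyped are dropped. The threshold is inclusive (exactly
  80 % is retained). The default coverage *mode* counts varieties;
  an acreage-share mode is available (`coverage_filter(..., mode="acreage")`)
  because "share of what is grown" admits both readings, and the two can
  disagree on the same county-year.
- **Renormalization.** After filtering, acreage proportions are
  renormalized over the genotyped varieties so `Σ A_i = 1`. Passing
  `totals=` instead divides by total planted acres, leaving `Σ A_i` at the
  genotyped share; the default is renormalization, which keeps `c_j` a
  proper convex combination.
- **Missing calls.** Real reduced-representation genotyping is never
  complete. The default policy fills a marker's missing calls with its
  mean across genotyped varieties; a strict policy raises instead. Calls
  other than {0, 1, missing} are rejected outright — the model is defined
  on binary inbred-variety calls, and silently recoding heterozygotes
  would change the estimand.

## Feature engineering and PCA

The design matrix is `[G | W | G×W]`: marker frequencies, the four weather
covariates, and all pairwise products (`M + 4 + 4M` columns; 43,779 at
M = 8,755). Columns are standardized to zero mean and unit variance on
training rows before PCA — the blocks mix °C, mm and frequencies, so
unscaled PCA would be dominated by precipitation. Zero-variance columns
are dropped first (logged). The PCA (default 85 components; a 1–300 grid
search utility `select_n_components` reproduces the selection procedure)
is fitted strictly on training rows; transforming held-out rows never
updates the fit, and a no-leakage test pins this.

## The stacked ensemble

Ten base learners in two families:

| slot | family | implementation |
|---|---|---|
| hist_boost | tree | histogram gradient boosting, 200 iters |
| gradient_boost | tree | gradient boosting, 200 trees, depth 3 |
| random_forest | tree | 200 trees, 50 % feature subsampling |
| adaboost | tree | 100 depth-4 trees, lr 0.5 |
| xgboost | tree | extreme gradient boosting, 200 trees, depth 4 |
| lasso | regression | L1, α = 1 (inputs standardized) |
| elastic_net | regression | α = 1, l1_ratio 0.5 |
| bayesian_ridge | regression | default priors |
| svr | regression | RBF, C = 10 (inputs and target standardized) |
| sgd | regression | squared loss, 2000 iters |

Slots are named by role, not library. Hyperparameters are deliberately
modest and overridable per slot via a config mapping; the architecture,
not per-learner tuning, is the object of interest.

The meta-learner is non-negative least squares over base predictions plus
a free intercept: weights are interpretable, and degenerate all-zero
solutions fall back to an equal-weight blend. To avoid layer-2 leakage the
meta-learner is fitted on out-of-fold base predictions (5-fold within the
training set); base learners are then refitted on the full training set.
Evaluation uses one seeded 75/25 split (a `repeats` argument provides
variance estimates). All learners are seeded and single-threaded, so
fit + predict is reproducible bit-for-bit.

`nse(obs, pred) = 1 − Σ(obs−pred)²/Σ(obs−mean)²` raises on constant
observations (undefined); Pearson r of a constant prediction is reported
as NaN rather than an arbitrary number.

## CVG backcasting and forecasting

Sliding windows sort varieties by release year (ties broken by variety
id) into bins of 20, step 1; classification groups partition by trait
flag. A CVG's pooled (equal-weight) frequency vector is paired with every
county-year weather row of a period, features are built exactly as in
training, and the relative change compares pooled means:
`100·(forecast_mean − backcast_mean)/backcast_mean`. The identity is
recomputed from the stored means, so it holds exactly for every result.

Projected rows with July maxima **strictly above 40 °C** are removed
before forecasting (40.0 is retained); the filter is applied per
county-year row — the least destructive of the defensible granularities
(row, year, trajectory) — and the drop count is carried into every result
so alternatives can be compared. Backcast and forecast means pool all
retained county-year rows rather than averaging county-then-year; with
near-balanced panels the difference is small, and pooling keeps the
estimator simple. The response-sweep utility holds three weather variables
at historical county means, sweeps the fourth, and flags grid points
outside the historical range as extrapolation.

## External trial evaluation

For each trial year, genotyped entries form an equal-weight yearly CVG;
the prediction at a (year, site) cell uses that CVG's frequencies with the
site-year weather, and the observed comparator is the mean trial yield of
the *same member varieties* at that cell — not of all entries, so the two
sides describe the same genetic material. Cells without weather are
skipped with a warning. Offsets between trial and production yield levels
affect RMSE but not r, which the tests pin down explicitly.

## The synthetic study system

The generator emulates the structure of the historical system: ~110
counties (20 at compact scale) observed over decades, 3–7 varieties per
county-year, contiguous variety market spans with geometric duration of
mean 6.3 years and no re-entry, acreage from lognormal draws, and weather
within the observed historical ranges (April mean 14.7–20.7 °C, April
rain 28.6–283 mm, July max 31.4–36.5 °C, July rain 48.2–179.8 mm) plus
per-decade drift (+0.29 °C April, +0.14 °C July, −1 to −2 mm rain).
Weather is a shared regional annual anomaly plus county noise — counties
are exchangeable; real spatial correlation structure along the Gulf Coast
is not emulated, and nothing downstream depends on it. Future scenarios
continue the process with a linear end-of-century warming ramp (mild:
+1.5 °C July; severe: +6 °C, deliberately pushing a share of rows past the
40 °C filter). A configurable fraction of varieties (default 10 %) is
withheld from the genotype matrix so the coverage filter has real work.

Yields come from an explicit linear ground truth,
`y = intercept + Σβ_j c_j + Σγ_k w_k + Σδ_{jk} c_j w_k + ε`, with 20
random marker effects (SD 150 kg/ha), weather main effects (+20 kg/ha/°C
April temperature, −60 kg/ha/°C July maximum, small precipitation
effects), and a positive interaction (δ = +40 kg/ha per unit c·w) between
July maximum and six "modern" markers whose frequency rises with release
year — modern varieties are heat-buffered by construction. An optional
piecewise-linear heat-stress term (`relu(july_tmax − t₀)`) provides a
nonlinear plug-in without changing any contract.

Two generator choices matter for identifiability and were made
deliberately:

- **County-specific variety preferences.** Counties draw persistent
  lognormal preference weights over varieties. Without them, county
  allele frequencies are almost a pure function of calendar year and
  therefore collinear with the weather trend; the G×W interaction is then
  unidentifiable and the fitted model can even invert the known CVG
  ordering. Cross-sectional adoption differences are also what real
  county data exhibit.
- **Noise calibration.** The default `noise_sd` of 900 kg/ha against a
  compact-scale signal SD of ≈1,740 kg/ha sets a theoretical NSE ceiling
  of ≈0.79; the achieved held-out NSE of ≈0.78 shows the ensemble
  extracting nearly all recoverable signal while operating in a skill
  regime comparable to historical county-yield modelling.

Trials add a persistent site effect (SD 250 kg/ha), a uniform management
bonus (+1,200 kg/ha; research plots outyield commercial production), and
plot noise (SD 350 kg/ha) on top of the same ground truth evaluated at
each variety's own genotype.

What passing tests show — and don't: the pipeline recovers a *linear*
G + W + G×W truth with exchangeable counties and MCAR missingness. Real
data add nonlinear weather response, spatially structured weather and
management, genotype-environment covariance from targeted breeding, and
informative missingness; skill there is an empirical question the
synthetic system cannot answer.

## Numerical choices and degenerate inputs

- Aggregation clips frequencies to [0, 1] against float drift; oracle
  tests compare the vectorized path to explicit double loops at 1e-12.
- PCA component requests are capped at min(rows, varying columns) when
  fitting the ensemble; `fit_pca` itself raises beyond the rank bound,
  and grid values beyond it are skipped with a warning during selection.
- Sliding-window ties in release year break by variety id, making CVG
  membership deterministic.
- An empty scenario table after filtering yields a result flagged
  invalid (NaN relative change) rather than an exception, so batch runs
  over many CVGs degrade gracefully.
- Constant targets, duplicate rows, permuted row order and repeated fits
  under one seed are all pinned by tests (bit-for-bit determinism).

## Known limitations

- With PCA-rotated inputs the tree and regression families perform
  comparably on this generator's truths — rotation removes the
  axis-aligned-split advantage, and with products already in the feature
  set linear learners are close to correctly specified. A family-level
  skill ordering is therefore not asserted anywhere; reports include
  per-learner metrics so users can compare families on their own data.
- Backcast/forecast extrapolates the fitted model to CVG frequency
  vectors (pure variety groups) that lie outside the convex hull of
  county bags, and to projected weather beyond the historical range.
  The 40 °C filter bounds the weather side; the genetic side is inherent
  to the CVG design and is why relative (within-CVG) change, not absolute
  level, is the reported statistic.
- The compact problem sizes used by the tests and the analysis drivers
  (20 counties × 30 years, 300 markers, 85 components) were chosen so the
  full chain runs in minutes; they preserve the structure, not the
  statistical power, of the full-size system.
- **The CVG ordering statistic is power-hungry.** The release-year
  gradient in relative yield change rides on the estimated G×W
  interaction coefficients, whose sampling noise at ~460 training rows
  exceeds the true ~2.5-point contrast: across realizations of the
  20-county system the Spearman rho of change vs window index is
  sign-unstable, and per-learner inspection shows even correctly
  specified linear learners inverting at unlucky draws. At ~900 rows
  (40 counties — closer to the ~2,800 county-years of real historical
  data) the sign is consistently positive across seeds. The forecasting
  stage of the test suite and the acceptance script therefore runs on the
  40-county system, while ensemble skill checks keep the 20-county size.
  The lesson transfers to real data: rankings of variety groups by
  forecast climate response carry the full uncertainty of the fitted
  interaction surface, and should be read with replication (or
  uncertainty bands), not as point estimates.
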