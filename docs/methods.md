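# Methods

`jorospread` analyses the North American invasion of the Jorō spider
(*Trichonephila clavata*), a large orb-weaver native to East Asia that was
introduced near Atlanta, Georgia around 2010 and has since spread across the
Southeast. The package implements three linked analyses — habitat-suitability
forecasting, directional spread measurement, and a community-impact
regression — together with synthetic-data generators that stand in for the
crowd-sourced occurrence records, bioclimate rasters, and field surveys the
real analyses consume.

## Data model and spatial conventions

All coordinates are WGS84 lon/lat degrees. Rasters are regular lon/lat grids
held in a `RasterLayer` (origin at the south-west corner, square cells,
row 0 = north) and read/written as ESRI ASCII grids, a plain-text format any
GIS ingests. Nodata is NaN in memory and a sentinel on disk. Point-in-cell
membership is half-open, `[min, max)` on both axes, so a point on a shared
edge belongs to exactly one cell; the same convention applies to study
extents. Distances are great-circle (haversine, R = 6371.0088 km); where a
local metric is needed (spatial blocks, the 10 km survey grid, km² cell
areas) degrees are converted at a reference latitude with a cos(latitude)
correction on the east–west axis. At the scales involved (≤ 500 km) this
approximation is accurate to well under 1%, far inside every tolerance used.

## Occurrence preparation

Community-science records cluster where observers live, not where spiders
are. Spatial thinning keeps at most one record per predictor-grid cell
(2.5 arc-min ≈ 4 km, so thinning and extraction share one grid); the record
kept in a cell is chosen uniformly at random under an explicit seed and the
output is ordered by cell index, so thinning is deterministic given the seed
and idempotent. Records from multiple portals are first deduplicated on
exact (lon, lat, date, species). Background points — the contrast sample a
presence–background SDM needs in place of true absences — are drawn
uniformly without replacement from non-nodata cells (default 50,000 per
region) and returned at cell centers.

## Predictor comparison and reduction

Native-vs-introduced climate differences are tested per predictor with
Mann–Whitney U (midrank ties, two-sided tie-corrected normal approximation,
no continuity correction) and summarized by the rank-biserial correlation
r_rb = 1 − 2U/(n₁n₂), classed large (> .5), moderate (> .3) or small on
|r_rb|.

Predictor reduction ranks each of the 20 candidates (19 bioclimate variables
plus maximum monthly wind speed) by the absolute log-odds-ratio of a
single-predictor logistic regression on standardized values, then loops:
compute all pairwise Pearson correlations among survivors; while any pair
has |r| > 0.7, remove the single worst-ranked predictor participating in a
flagged pair and repeat. One removal per pass keeps the procedure
order-deterministic; ties in |log OR| break by input column order. The
threshold is applied to |r|: a strong negative correlation is just as
redundant as a positive one. A perfectly separating predictor is maximally
informative and is ranked first (flagged); any other non-convergent fit is
ranked last (flagged). Predictors are standardized before the bivariate
fits so the odds ratios are comparable across variables with different
units.

## The SDM ensemble

Four presence–background models are fit on centered-and-scaled predictors
(sample sd, n−1) and averaged cell-wise with equal weights:

* **GLM** — binomial regression with linear + quadratic terms per predictor
  (the quadratic allows the unimodal niche responses typical of climate
  predictors; the exact term structure is a package choice).
* **GAM** — binomial fit with a penalized B-spline smooth (6 basis
  functions, cubic) per predictor plus intercept, fixed modest penalty.
  Projection clips inputs to the training span, where the spline basis is
  defined.
* **maxent-like** — the penalized-logistic formulation of maximum-entropy
  modelling: linear, quadratic, and hinge features (8 interior-quantile
  knots per predictor, forward and reverse) under an L1 penalty whose
  strength shrinks with presence count (C = √n_presence). With linear
  features only and the penalty removed it reproduces the linear GLM's cell
  ranking, which is asserted as a test.
* **down-sampled random forest** — 1000 full classification trees, each
  grown on a balanced bootstrap (per-class draw = number of presences, the
  data-derived analogue of a fixed per-class sampsize), √p candidate
  predictors per split; prediction is the mean tree vote.

Standardization parameters from training are reapplied verbatim when
projecting onto another region's rasters; nodata propagates through
extraction, projection, and averaging.

**Spatial-block cross-validation.** Random CV folds leak information when
data are spatially autocorrelated, inflating AUC. Points are assigned to
square blocks (default edge 860 km, converted to degrees at the dataset
mid-latitude); whole blocks are shuffled and dealt round-robin into k = 10
folds, so each fold is geographically disjoint from its training data and
no fold is empty while block counts allow. Held-out performance is AUC (the
normalized Mann–Whitney rank statistic over presence vs background scores)
and MAE against the 0/1 labels. A held-out fold with a single class is
skipped and logged. A designed-bias test confirms the point: on clustered,
autocorrelated synthetic data, block CV's AUC is at or below random-split
CV's on average.

A note on attainable AUC: because the background sample includes suitable
cells, presence–background AUC is capped by how rare suitable habitat is
(roughly (1 + F(t))/2 for a niche occupying the tail beyond t). Synthetic
benchmarks that expect AUC > 0.9 therefore use a landscape whose suitable
fraction is ~10%.

## Range expansion

The invasion centroid is the arithmetic mean of the nine earliest documented
introduction coordinates (a configuration input; tests use a synthetic
stand-in). Every occurrence is classed NE/SE/NW/SW by the sign of its
lon/lat offset from the centroid, with ties (≥) going north/east.

**Distance method.** Per calendar year (2018–2022) and quadrant, the leading
edge is the mean haversine distance of the up-to-three farthest records;
the number actually used is reported, and an empty year×quadrant cell is a
missing value, not zero. Per-quadrant expansion rates are OLS slopes of
edge distance on year. Observation sets are per-calendar-year by default
(cumulative-through-year is a config switch; the two differ only when a
year's edge regresses).

**Area method.** Per year, after within-year thinning, an isotropic
bivariate Gaussian KDE is evaluated in degree space at the reference
bandwidth h = 0.5·(sd_lon + sd_lat)·n^(−1/6) (sample sds; the formula is
stated in degrees, so the KDE stays in degrees for fidelity, and areas are
converted afterwards). The evaluation grid (default 512²) pads the point
bounding box by 4h, which retains > 99.99% of the kernel mass. The 0.99
isopleth is the grid-based highest-density region: cells sorted by density,
threshold at the cumulative-mass quantile. Areas are summed per cell in km²
with the cos(latitude) correction and partitioned exactly by quadrant of
the cell center; boundary polygons come from marching-squares contours for
GeoJSON export. Degenerate inputs fail loudly: h = 0 (coincident points),
fewer than 5 points in a year, or a level outside (0, 1).

## Diversity impact

Per transect survey, species richness, Shannon's H = −Σ pᵢ ln pᵢ and
Simpson's D = 1 − Σ pᵢ² are computed over native species only — the
invader's local dominance would otherwise turn diversity shifts into pure
evenness artifacts. Richness also excludes the invader by default (a config
flag restores it). Two invasion-history covariates are attached: distance
from the centroid in meters, and years present — the survey point's 10 km
grid cell is looked up in the invader's occurrence history, and the
covariate counts calendar years from the cell's first record to the
analysis date, with a first record in the analysis year scoring 1 (present
that summer) and an empty cell scoring 0.

Moran's I on model residuals guards the non-spatial regressions: weights
are binary row-standardized, built either from k-nearest neighbors (every
site guaranteed a neighbor) or from a 10 km radius (an isolated site is
joined to its nearest neighbor and logged); the p-value uses the two-sided
normal approximation under the randomization null, whose variance involves
the empirical kurtosis. Constant residuals are an error, not a zero.

The model suite crosses response (richness — Poisson log-link; Shannon,
Simpson — Gaussian OLS) with predictor-of-interest (distance, years) and
structure (main effects; density×predictor interaction with both main
effects retained), always adjusting for temperature, windspeed, rain in the
last 24 h, and Julian day (1-based from January 1). Models are ranked by
AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1), with k counting the residual variance
for Gaussian fits and ΔAICc computed within each response's suite; n ≤ k+1
is an error. Default reports surface only the interaction coefficient —
the adjusted covariates' coefficients are confounder adjustments, not
effect estimates, and printing them invites the "table 2" misreading
(full coefficients sit behind a flag). Scenario predictions evaluate the
fitted model at specified covariate settings (others at sample means), on
the response scale with delta-method 95% intervals.

## Synthetic data

The generators define the package's test conditions:

* **Landscapes** — predictors are Gaussian random fields (white noise
  smoothed by a Gaussian kernel, σ = 8 cells, standardized), and truth is
  logistic in them with configurable linear/quadratic coefficients. The
  default grid is 100×100 cells of 0.1° over a 10°×10° window.
* **Spread** — per year and quadrant the envelope radius is
  initial 5 km + rate·(year − 2017), with rates NE/NW/SE/SW =
  40/25/10/12 km/yr and 2000 points per year placed uniformly over the
  envelope area (radius = r_max·√U), so the top-3 order statistics sit near
  the true edge. The rates build in the observed faster-north-than-south
  asymmetry.
* **Surveys** — 103 sites on a 150 km disc around the centroid; covariates
  from plausible late-season ranges; 18 native species with Dirichlet
  community shares, each species' count Poisson with a shared log-linear
  effect structure including a pop-density×years interaction
  (default −0.12 on the z-density × centered-years scale, matching the
  inferential strength the study reports at n = 103, |z| ≈ 2); the
  invader's count decays exponentially with distance from the centroid.
  Because per-species means are small (λ ≈ 0.3), richness inherits the
  abundance effects with only mild (~10%) attenuation.

What the generators do not emulate: real bioclimate covariance structure,
observer phenology, detection error, within-transect overdispersion, or
coastlines/political borders. Passing recovery tests therefore demonstrates
correctness of the estimators under the stated generative assumptions, not
robustness to every field complication.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately modest sizes chosen as adequate
for their statistical purpose: SDM benchmarks at n = 2000 points with 5-fold
spatial blocks (860 km blocks need a continental extent; the synthetic
window uses 250 km), 100 forest trees in tests (1000, the analysis default,
in the acceptance script), KDE grids of 256² in tests, 100 replicates for
power/coverage rates, 20 for slower model-level tendencies. Random draws
all flow from explicit integer seeds; `numpy.random.default_rng` throughout.
Ties: thinning keeps a uniform random record per cell; quadrant boundaries
go north/east; equal |log OR| ranks break by column order.

## Known limitations

* The maxent-like model is the standard penalized-logistic equivalent, not
  a bit-for-bit reimplementation of any packaged Maxent; comparisons to it
  are property-based (ranking agreement, bounds), not value-based.
* Reproducing the study's own CV statistics, Table-1 coefficients, and
  scenario numbers requires the archived occurrence/raster snapshot; with
  synthetic stand-ins the pipeline checks estimator recovery against known
  truth instead.
* Equal-area handling is the cos(latitude) local approximation, adequate at
  regional scales; a projected CRS would be needed for continental-scale
  area accounting.
* The nine founding coordinates of the introduction are not shipped; they
  are a required configuration input for analyses of real data.
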