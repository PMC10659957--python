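# jorospread

Analysis pipeline for the North American invasion of the Jorō spider
(*Trichonephila clavata*), a large East Asian orb-weaver introduced near
Atlanta, Georgia around 2010. The package is aimed at spatial ecologists
working with crowd-sourced occurrence data (iNaturalist/GBIF-style exports),
bioclimate rasters, and transect surveys, and implements three analyses:

1. **Habitat suitability** (`jorospread.predictors`, `jorospread.sdm`) —
   an ensemble of four presence–background species distribution models
   (GLM with quadratic terms, penalized-spline GAM, a maxent-style
   penalized logistic model with hinge features, and a down-sampled
   1000-tree random forest) trained on native-range occurrences against
   50,000 background points, evaluated by spatial-block cross-validation
   (860 km blocks, k = 10, reporting AUC and MAE), and projected onto the
   introduced range. Candidate predictors are first reduced by ranking
   bivariate logistic odds ratios and iteratively removing the worst-ranked
   member of any pair with Pearson |r| > .7. Native/introduced climate
   contrasts use Mann–Whitney U with the rank-biserial effect size
   r_rb = 1 − 2U/(n₁n₂).
2. **Range expansion** (`jorospread.spread`) — directional spread from the
   invasion centroid measured two ways: the leading edge (mean haversine
   distance of the three farthest records per year and quadrant) and the
   occupied area (0.99 isopleth of a Gaussian KDE at the reference
   bandwidth h = 0.5·(sd_lon + sd_lat)·n^(−1/6), partitioned by quadrant,
   in km²).
3. **Diversity impact** (`jorospread.diversity`) — native orb-weaver
   richness, Shannon H and Simpson D per transect (invader excluded),
   regressed on invasion history (distance from centroid; years present in
   the site's 10 km cell) with adjustment covariates and a human population
   density × predictor interaction; Poisson/Gaussian model suites ranked by
   AICc, Moran's I residual checks, and scenario predictions with 95%
   intervals.

`jorospread.simulate` generates all inputs with known ground truth —
smooth random-field landscapes with logistic suitability, a radially
expanding invasion with direction-specific rates, and Poisson transect
surveys with a known interaction — so the full pipeline runs and is tested
without any downloads. `jorospread.geodata` holds the shared containers
(occurrences, plain-text ESRI ASCII rasters) plus thinning, background
sampling, and extraction.

## Worked example

Estimate directional expansion rates from a simulated invasion and fit the
survey model suite:

```python
import jorospread as j

spec = j.simulate.SpreadSpec()            # NE/NW/SE/SW = 40/25/10/12 km/yr
occs, truth = j.simulate.simulate_spread(spec, seed=42)
series = j.spread.leading_edge_series(occs, spec.centroid, spec.years)
rates = j.spread.expansion_rates(series)
for q in ("NE", "NW", "SE", "SW"):
    print(f"{q}: estimated {rates[q]:5.1f} km/yr (true {spec.rates[q]:.0f})")

table, beta = j.simulate.simulate_surveys(seed=42)
table = j.simulate.attach_diversity(table)
fits = j.diversity.fit_suite(table)
best = min((f for f in fits if f.response == "richness"), key=lambda f: f.aicc)
print(f"best richness model: predictor={best.predictor}, "
      f"interaction={best.interaction}, AICc={best.aicc:.1f}")
term = best.interaction_term
print(f"interaction coefficient {best.coefficients[term]:.4f} "
      f"(SE {best.bse[term]:.4f}, true {beta['interaction']})")
```

prints

```
NE: estimated  39.9 km/yr (true 40)
NW: estimated  24.9 km/yr (true 25)
SE: estimated  10.0 km/yr (true 10)
SW: estimated  12.0 km/yr (true 12)
best richness model: predictor=years_present, interaction=True, AICc=422.9
interaction coefficient -0.0007 (SE 0.0003, true -0.12)
```

The per-quadrant leading-edge slopes recover the generative rates to within
a few percent, reproducing the built-in faster-north-than-south asymmetry.
AICc selects the interaction model that generated the data. The fitted
interaction is per person/km² of raw density while the generative value is
per standard deviation of density (SD ≈ 174 persons/km² here, so
−0.0007 × 174 ≈ −0.12): effects on unscaled covariates print as tiny
magnitudes even when substantively strong.

A thin CLI mirrors the pipeline stages:

```sh
jorospread simulate spread --seed 1 --out data/
jorospread spread data/spread_occurrences.csv --method distance \
    --centroid -83.8 34.1 --out series.csv
jorospread survey-analysis surveys.csv --response richness --out suite.csv
```

## Layout

```
src/jorospread/
  geodata.py     occurrences, rasters (ESRI ASCII), thinning, background
  predictors.py  climate comparison, odds-ratio ranking, reduction loop
  sdm.py         four SDM families, spatial-block CV, projection, averaging
  spread.py      centroid, quadrants, leading edge, KDE isopleth areas
  diversity.py   indices, covariates, Moran's I, AICc suite, scenarios
  simulate.py    landscape / spread / survey generators with ground truth
  cli.py         thin click CLI over the above
docs/methods.md  model assumptions, parameter choices, limitations
```
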