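"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators mirror the structure of the real data streams:

* ``make_landscape`` — co-registered smooth predictor rasters (Gaussian
  random fields) plus the true logistic suitability surface they induce;
* ``simulate_spread`` — a radially expanding invasion with
  direction-specific km/yr rates and dated, clustered occurrence sampling;
* ``simulate_surveys`` — transect survey tables whose species counts are
  Poisson with a log-mean following the diversity analysis's model form,
  including a population-density x invasion-history interaction.

Every generator is reproducible under (spec, seed) and returns its ground
truth alongside the data, so estimator-recovery tests can compare against
the generative values rather than re-derived ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from datetime import date as _date, timedelta

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .geodata import KM_PER_DEG, Extent, Occurrence, RasterLayer
from .spread import QUADRANTS, InvasionCentroid

# ------------------------------------------------------------------ landscape


@dataclass
class LandscapeSpec:
    extent: Extent = dc_field(
        default_factory=lambda: Extent(-90.0, 30.0, -80.0, 40.0)
    )
    cell: float = 0.1
    predictors: tuple[str, ...] = ("bio6", "bio8", "bio15", "bio18", "wind_max")
    length_scale: float = 8.0     # smoothing sigma, in cells
    variance: float = 1.0         # 0 -> constant (flat) fields
    intercept: float = -1.0
    #: name -> (linear, quadratic) coefficient on the standardized field
    coefficients: dict[str, tuple[float, float]] = dc_field(
        default_factory=lambda: {
            "bio6": (2.0, 0.0),
            "bio8": (1.0, -0.5),
            "bio15": (-1.0, 0.0),
            "bio18": (0.5, 0.0),
            "wind_max": (-0.5, 0.0),
        }
    )


def _gaussian_field(shape: tuple[int, int], length_scale: float, variance: float,
                    rng: np.random.Generator) -> np.ndarray:
    if variance == 0:
        return np.zeros(shape)
    noise = rng.standard_normal(shape)
    f = gaussian_filter(noise, sigma=length_scale, mode="wrap")
    f = (f - f.mean()) / f.std()
    return f * np.sqrt(variance)


def make_landscape(
    spec: LandscapeSpec | None = None, seed: int = 0
) -> tuple[list[RasterLayer], RasterLayer]:
    """Generate predictor rasters and the true suitability raster.

    Suitability is logistic in the standardized fields:
    ``p = expit(b0 + sum_j b1j z_j + b2j z_j^2)``.
    """
    spec = spec or LandscapeSpec()
    rng = np.random.default_rng(seed)
    ext = spec.extent
    n_cols = int(round((ext.max_lon - ext.min_lon) / spec.cell))
    n_rows = int(round((ext.max_lat - ext.min_lat) / spec.cell))
    layers = []
    eta = np.full((n_rows, n_cols), spec.intercept)
    for name in spec.predictors:
        z = _gaussian_field((n_rows, n_cols), spec.length_scale, spec.variance, rng)
        b1, b2 = spec.coefficients.get(name, (0.0, 0.0))
        eta = eta + b1 * z + b2 * z**2
        layers.append(
            RasterLayer(name=name, x_min=ext.min_lon, y_min=ext.min_lat,
                        cell=spec.cell, values=z)
        )
    truth = RasterLayer(
        name="true_suitability", x_min=ext.min_lon, y_min=ext.min_lat,
        cell=spec.cell, values=expit(eta),
    )
    return layers, truth


@dataclass
class BiasSpec:
    """Observation-effort surface: Gaussian bumps over a uniform floor."""

    clusters: tuple[tuple[float, float, float, float], ...] = ()  # lon, lat, sigma_deg, weight
    floor: float = 1.0


def bias_surface(template: RasterLayer, bias: BiasSpec | None) -> np.ndarray:
    if bias is None:
        return np.ones_like(template.values)
    rows, cols = np.indices(template.values.shape)
    lons = template.x_min + (cols + 0.5) * template.cell
    lats = template.y_min + (template.n_rows - rows - 0.5) * template.cell
    surf = np.full(template.values.shape, bias.floor)
    for clon, clat, sigma, weight in bias.clusters:
        surf += weight * np.exp(
            -((lons - clon) ** 2 + (lats - clat) ** 2) / (2 * sigma**2)
        )
    return surf


def sample_presences(
    truth: RasterLayer,
    n: int,
    bias: BiasSpec | None = None,
    seed: int = 0,
    year: int = 2022,
    source: str = "synthetic",
) -> list[Occurrence]:
    """Draw presence records with probability ∝ suitability x observer bias."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    w = np.where(np.isnan(truth.values), 0.0, truth.values) * bias_surface(truth, bias)
    flat = w.ravel()
    if flat.sum() <= 0:
        raise ValueError("suitability x bias surface has no positive mass")
    pick = rng.choice(flat.size, size=n, replace=True, p=flat / flat.sum())
    rows, cols = np.unravel_index(pick, w.shape)
    occs = []
    for i, (r, c) in enumerate(zip(rows, cols)):
        clon, clat = truth.cell_center(int(r), int(c))
        jlon, jlat = rng.uniform(-0.5, 0.5, 2) * truth.cell
        day = int(rng.integers(0, 365))
        occs.append(
            Occurrence(
                record_id=f"syn-{seed}-{i}",
                lon=clon + jlon, lat=clat + jlat,
                date=_date(year, 1, 1) + timedelta(days=day),
                source=source,
            )
        )
    return occs


# -------------------------------------------------------------------- spread

# arc of bearings (radians, measured from east counter-clockwise) per quadrant
_QUADRANT_ARCS = {
    "NE": (0.0, np.pi / 2),
    "NW": (np.pi / 2, np.pi),
    "SW": (np.pi, 3 * np.pi / 2),
    "SE": (3 * np.pi / 2, 2 * np.pi),
}


@dataclass
class SpreadSpec:
    centroid: InvasionCentroid = dc_field(
        default_factory=lambda: InvasionCentroid(lon=-83.8, lat=34.1)
    )
    #: direction-specific radial expansion, km/yr
    rates: dict[str, float] = dc_field(
        default_factory=lambda: {"NE": 40.0, "NW": 25.0, "SE": 10.0, "SW": 12.0}
    )
    years: tuple[int, ...] = (2018, 2019, 2020, 2021, 2022)
    year_zero: int = 2017          # envelope radius is rate * (year - year_zero)
    initial_radius_km: float = 5.0
    n_per_year: int = 2000


def simulate_spread(
    spec: SpreadSpec | None = None, seed: int = 0
) -> tuple[list[Occurrence], dict[tuple[int, str], float]]:
    """Dated occurrences of a radially expanding invasion.

    Each year, points fill the quadrant-wise envelope of radius
    ``initial_radius + rate_q * (year - year_zero)`` uniformly over area
    (radius = r_max * sqrt(U)), so the farthest observations sit near the
    true edge. Returns the records and the true (year, quadrant) -> edge-km
    map used by recovery tests.
    """
    spec = spec or SpreadSpec()
    rng = np.random.default_rng(seed)
    c = spec.centroid
    cos_lat = np.cos(np.radians(c.lat))
    occs: list[Occurrence] = []
    truth: dict[tuple[int, str], float] = {}
    i = 0
    for year in spec.years:
        for q in QUADRANTS:
            r_max = spec.initial_radius_km + spec.rates[q] * (year - spec.year_zero)
            truth[(year, q)] = r_max
        for _ in range(spec.n_per_year):
            q = QUADRANTS[rng.integers(len(QUADRANTS))]
            r_max = truth[(year, q)]
            theta = rng.uniform(*_QUADRANT_ARCS[q])
            r = r_max * np.sqrt(rng.uniform())
            dx, dy = r * np.cos(theta), r * np.sin(theta)
            day = int(rng.integers(90, 330))  # active season
            occs.append(
                Occurrence(
                    record_id=f"spread-{seed}-{i}",
                    lon=c.lon + dx / (KM_PER_DEG * cos_lat),
                    lat=c.lat + dy / KM_PER_DEG,
                    date=_date(year, 1, 1) + timedelta(days=day),
                )
            )
            i += 1
    return occs, truth


# ------------------------------------------------------------------- surveys


@dataclass
class SurveySpec:
    n_locations: int = 103
    n_species: int = 19            # includes the invader
    centroid: InvasionCentroid = dc_field(
        default_factory=lambda: InvasionCentroid(lon=-83.8, lat=34.1)
    )
    survey_radius_km: float = 150.0
    #: expected native individuals per site at covariate means
    base_abundance: float = 6.0
    #: log-scale effects; pop_density enters z-scored, years in raw years
    beta: dict[str, float] = dc_field(
        default_factory=lambda: {
            "temp_c": 0.02,
            "windspeed_kph": -0.02,
            "rain24h_cm": -0.05,
            "julian_day": -0.003,
            "pop_density": 0.05,
            "years_present": -0.10,
            "interaction": -0.12,
        }
    )
    invader_base: float = 8.0      # expected invader count at the centroid
    invader_decay_km: float = 60.0


_NATIVE_SPECIES = (
    "Micrathena_mitrata", "Neoscona_crucifera", "Verrucosa_arenata",
    "Araneus_marmoreus", "Leucauge_venusta", "Micrathena_gracilis",
    "Trichonephila_clavipes", "Gasteracantha_cancriformis", "Argiope_aurantia",
    "Mangora_placida", "Neoscona_domiciliorum", "Micrathena_sagittata",
    "Araneus_bicentenarius", "Acanthepeira_stellata", "Cyclosa_turbinata",
    "Eustala_anastera", "Larinioides_cornutus", "Uloborus_glomosus",
)


def simulate_surveys(
    spec: SurveySpec | None = None, seed: int = 0
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Transect survey table with Poisson species counts and known effects.

    Site covariates are drawn from plausible late-season ranges; each
    native species' count is Poisson with log-mean sharing the spec's
    centered covariate effects (so community richness and diversity inherit
    them); the invader's count decays with distance from the centroid.
    Returns the table and the true coefficient dictionary.
    """
    spec = spec or SurveySpec()
    rng = np.random.default_rng(seed)
    n = spec.n_locations
    c = spec.centroid
    cos_lat = np.cos(np.radians(c.lat))

    # site locations: uniform over a disc around the centroid
    r = spec.survey_radius_km * np.sqrt(rng.uniform(size=n))
    th = rng.uniform(0, 2 * np.pi, n)
    lon = c.lon + r * np.cos(th) / (KM_PER_DEG * cos_lat)
    lat = c.lat + r * np.sin(th) / KM_PER_DEG
    dist_m = r * 1000.0

    temp = rng.normal(24.0, 4.0, n)
    wind = np.abs(rng.normal(6.0, 3.0, n))
    rain = rng.exponential(0.4, n)
    julian = rng.integers(241, 313, n).astype(float)  # late Aug - early Nov
    pop = np.exp(rng.normal(4.5, 1.0, n))             # persons / km^2
    pop_z = (pop - pop.mean()) / pop.std()
    # longer presence nearer the introduction site, with local noise
    years = np.clip(
        np.round(5.0 * (1.0 - dist_m / (spec.survey_radius_km * 1.3e3))
                 + rng.normal(0, 0.7, n)),
        0, 6,
    )

    b = spec.beta
    eta = (
        b["temp_c"] * (temp - temp.mean())
        + b["windspeed_kph"] * (wind - wind.mean())
        + b["rain24h_cm"] * (rain - rain.mean())
        + b["julian_day"] * (julian - julian.mean())
        + b["pop_density"] * pop_z
        + b["years_present"] * (years - years.mean())
        + b["interaction"] * pop_z * (years - years.mean())
    )
    n_native = spec.n_species - 1
    natives = _NATIVE_SPECIES[:n_native] + tuple(
        f"Araneidae_sp_{j:02d}" for j in range(len(_NATIVE_SPECIES), n_native)
    )
    # species share of the community; uneven, as real communities are
    share = rng.dirichlet(np.full(n_native, 0.8))
    counts = {
        f"count_{sp}": rng.poisson(spec.base_abundance * share[j] * np.exp(eta))
        for j, sp in enumerate(natives)
    }
    lam_inv = spec.invader_base * np.exp(
        -dist_m / (spec.invader_decay_km * 1000.0) + 0.3 * pop_z
    )
    counts["count_Trichonephila_clavata"] = rng.poisson(lam_inv)

    table = pd.DataFrame(
        {
            "location_id": [f"site-{i:03d}" for i in range(n)],
            "lon": lon, "lat": lat,
            "date": [
                (_date(2022, 8, 29) + timedelta(days=int(d))).isoformat()
                for d in julian - 241
            ],
            "time": "10:00",
            "temp_c": temp, "windspeed_kph": wind, "rain24h_cm": rain,
            "julian_day": julian, "pop_density": pop,
            "distance_m": dist_m, "years_present": years,
            **counts,
        }
    )
    return table, dict(spec.beta)


def attach_diversity(table: pd.DataFrame, species_prefix: str = "count_",
                     invader: str = "Trichonephila_clavata") -> pd.DataFrame:
    """Add richness/shannon/simpson columns over the native count columns."""
    from .diversity import richness, shannon, simpson

    sp_cols = [
        col for col in table.columns
        if col.startswith(species_prefix) and col != f"{species_prefix}{invader}"
    ]
    counts = table[sp_cols].to_numpy(dtype=float)
    out = table.copy()
    out["richness"] = [richness(row) for row in counts]
    out["shannon"] = [shannon(row) for row in counts]
    out["simpson"] = [simpson(row) for row in counts]
    return out
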