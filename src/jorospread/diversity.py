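"""Native orb-weaver diversity vs invasion history at transect surveys.

Per survey we compute species richness, Shannon's H and Simpson's D over
the native species (the invader is excluded so that its local dominance
cannot mask evenness changes in the rest of the community), derive two
invasion-history covariates (distance from the invasion centroid; years the
invader has been present in the survey's 10 km grid cell), check model
residuals for spatial autocorrelation with Moran's I, fit a suite of
linear / Poisson models with and without a population-density interaction,
rank them by AICc, and evaluate scenario predictions from the best fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date as _date

import numpy as np
import pandas as pd

from .geodata import KM_PER_DEG, Occurrence
from .spread import InvasionCentroid, haversine_km

logger = logging.getLogger(__name__)

INVADER = "Trichonephila clavata"

RESPONSES = ("richness", "shannon", "simpson")
PREDICTORS_OF_INTEREST = ("distance_m", "years_present")
ADJUSTMENT_TERMS = ("temp_c", "windspeed_kph", "rain24h_cm", "julian_day")


def shannon(counts) -> float:
    """Shannon's H = -sum p_i ln p_i over species with count > 0."""
    c = np.asarray(list(counts.values()) if isinstance(counts, dict) else counts,
                   dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    c = c[c > 0]
    if c.size == 0:
        return 0.0
    p = c / c.sum()
    return float(-(p * np.log(p)).sum())


def simpson(counts) -> float:
    """Simpson's diversity D = 1 - sum p_i^2 (probability two draws differ)."""
    c = np.asarray(list(counts.values()) if isinstance(counts, dict) else counts,
                   dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    c = c[c > 0]
    if c.size == 0:
        return 0.0
    p = c / c.sum()
    return float(1.0 - (p**2).sum())


def richness(counts) -> int:
    c = np.asarray(list(counts.values()) if isinstance(counts, dict) else counts,
                   dtype=float)
    return int((c > 0).sum())


def diversity_metrics(counts: dict[str, int], exclude: tuple[str, ...] = (INVADER,)
                      ) -> dict[str, float]:
    """Richness, Shannon and Simpson over the native community."""
    native = {sp: n for sp, n in counts.items() if sp not in exclude}
    return {
        "richness": richness(native),
        "shannon": shannon(native),
        "simpson": simpson(native),
    }


def summarize_surveys(table: pd.DataFrame, species_prefix: str = "count_"
                      ) -> pd.DataFrame:
    """Per-species occupancy and abundance summary across survey sites.

    Returns one row per species with: total individuals, number and
    percentage of sites where present, and mean individuals per site
    (over all sites, as reported in field-survey summaries).
    """
    sp_cols = [c for c in table.columns if c.startswith(species_prefix)]
    if not sp_cols:
        raise ValueError(f"no species columns with prefix '{species_prefix}'")
    n_sites = len(table)
    rows = []
    for col in sp_cols:
        c = table[col].to_numpy(dtype=float)
        rows.append(
            {
                "species": col[len(species_prefix):],
                "total": int(c.sum()),
                "n_sites_present": int((c > 0).sum()),
                "occupancy_pct": round(100.0 * (c > 0).sum() / n_sites, 1),
                "mean_per_site": float(c.sum() / n_sites),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("total", ascending=False)
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------- covariates

def _grid_index(lon: float, lat: float, lat0: float, grid_km: float
                ) -> tuple[int, int]:
    x = lon * KM_PER_DEG * np.cos(np.radians(lat0))
    y = lat * KM_PER_DEG
    return int(np.floor(x / grid_km)), int(np.floor(y / grid_km))


def years_present(
    invader_occs: list[Occurrence],
    survey_lon: float,
    survey_lat: float,
    as_of: _date,
    grid_km: float = 10.0,
    lat0: float | None = None,
) -> int:
    """Years the invader has been present in the survey's grid cell.

    The survey area is tiled with ``grid_km`` square cells (local equal-area
    metric at ``lat0``); the covariate is the count of calendar years from
    the cell's first invader observation to ``as_of``. A first observation
    in the ``as_of`` year itself counts as 1 (it was present that summer);
    a cell with no observation scores 0.
    """
    if lat0 is None:
        lat0 = survey_lat
    cell = _grid_index(survey_lon, survey_lat, lat0, grid_km)
    first: int | None = None
    for o in invader_occs:
        if _grid_index(o.lon, o.lat, lat0, grid_km) == cell:
            if first is None or o.date.year < first:
                first = o.date.year
    if first is None:
        return 0
    return max(1, as_of.year - first)


def invasion_covariates(
    table: pd.DataFrame,
    invader_occs: list[Occurrence],
    centroid: InvasionCentroid,
    as_of: _date,
    grid_km: float = 10.0,
) -> pd.DataFrame:
    """Attach distance-from-centroid (m) and years-present to survey rows."""
    out = table.copy()
    lat0 = float(out["lat"].mean())
    out["distance_m"] = [
        haversine_km((lo, la), (centroid.lon, centroid.lat)) * 1000.0
        for lo, la in zip(out["lon"], out["lat"])
    ]
    out["years_present"] = [
        years_present(invader_occs, lo, la, as_of, grid_km, lat0)
        for lo, la in zip(out["lon"], out["lat"])
    ]
    return out


# ------------------------------------------------------------------ Moran's I

def knn_weights(lons: np.ndarray, lats: np.ndarray, k: int = 1) -> np.ndarray:
    """Binary row-standardized k-nearest weights (every site has a neighbor)."""
    n = len(lons)
    d = np.array([
        [haversine_km((lons[i], lats[i]), (lons[j], lats[j])) for j in range(n)]
        for i in range(n)
    ])
    np.fill_diagonal(d, np.inf)
    w = np.zeros((n, n))
    for i in range(n):
        for j in np.argsort(d[i])[:k]:
            w[i, j] = 1.0
    return w / w.sum(axis=1, keepdims=True)


def radius_weights(lons: np.ndarray, lats: np.ndarray, radius_km: float = 10.0
                   ) -> np.ndarray:
    """Binary row-standardized weights over all sites within ``radius_km``.

    A site with no neighbor inside the radius is joined to its nearest
    neighbor (and logged) so the weight matrix has no empty rows.
    """
    n = len(lons)
    d = np.array([
        [haversine_km((lons[i], lats[i]), (lons[j], lats[j])) for j in range(n)]
        for i in range(n)
    ])
    np.fill_diagonal(d, np.inf)
    w = (d <= radius_km).astype(float)
    for i in range(n):
        if w[i].sum() == 0:
            j = int(np.argmin(d[i]))
            w[i, j] = 1.0
            logger.info("radius_weights: site %d isolated; joined to %d", i, j)
    return w / w.sum(axis=1, keepdims=True)


def morans_i(values: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Global Moran's I with a two-sided randomization normal-approx p-value.

    I = (n / S0) * (sum_ij w_ij z_i z_j / sum_i z_i^2), z centered values.
    """
    z = np.asarray(values, dtype=float)
    n = z.size
    if n < 3:
        raise ValueError("need at least 3 locations")
    z = z - z.mean()
    s2 = (z**2).sum()
    if s2 == 0:
        raise ValueError("values have zero variance")
    s0 = w.sum()
    i_obs = (n / s0) * float(z @ w @ z) / s2
    # moments under the randomization null
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2w = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    e_i = -1.0 / (n - 1)
    b2 = n * (z**4).sum() / s2**2
    num = n * ((n**2 - 3 * n + 3) * s1 - n * s2w + 3 * s0**2) - b2 * (
        (n**2 - n) * s1 - 2 * n * s2w + 6 * s0**2
    )
    den = (n - 1) * (n - 2) * (n - 3) * s0**2
    var_i = num / den - e_i**2
    from scipy.stats import norm

    zscore = (i_obs - e_i) / np.sqrt(var_i)
    return float(i_obs), float(2 * norm.sf(abs(zscore)))


# -------------------------------------------------------------- model suite

@dataclass
class ModelFit:
    response: str
    predictor: str           # distance_m | years_present
    family: str              # poisson | gaussian
    interaction: bool
    coefficients: pd.Series
    bse: pd.Series
    loglik: float
    k: int
    n: int
    aicc: float
    delta_aicc: float = np.nan
    result: object = None    # statsmodels results, for predictions

    @property
    def interaction_term(self) -> str:
        return f"pop_density:{self.predictor}"


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample Akaike criterion: AIC + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for k={k}, n={n} (n - k - 1 <= 0)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _formula(response: str, predictor: str, interaction: bool) -> str:
    base = " + ".join(ADJUSTMENT_TERMS)
    if interaction:
        return f"{response} ~ {base} + pop_density * {predictor}"
    return f"{response} ~ {base} + pop_density + {predictor}"


def fit_suite(table: pd.DataFrame) -> list[ModelFit]:
    """Fit the response x predictor x structure model suite, ranked by AICc.

    Richness is a count and uses Poisson log-link regression; Shannon and
    Simpson are continuous and use Gaussian linear models. Every model
    adjusts for temperature, windspeed, rain in the last 24 h, Julian day
    and human population density; the interaction variants add
    density x predictor-of-interest (with both main effects retained).
    Delta-AICc is computed within each response's suite.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    n = len(table)
    fits: list[ModelFit] = []
    for response in RESPONSES:
        group: list[ModelFit] = []
        for predictor in PREDICTORS_OF_INTEREST:
            for interaction in (False, True):
                f = _formula(response, predictor, interaction)
                if response == "richness":
                    res = smf.glm(f, data=table, family=sm.families.Poisson()).fit()
                    family = "poisson"
                    k = len(res.params)
                else:
                    res = smf.ols(f, data=table).fit()
                    family = "gaussian"
                    k = len(res.params) + 1  # + residual variance
                group.append(
                    ModelFit(
                        response=response, predictor=predictor, family=family,
                        interaction=interaction,
                        coefficients=res.params, bse=res.bse,
                        loglik=float(res.llf), k=k, n=n,
                        aicc=aicc(float(res.llf), k, n),
                        result=res,
                    )
                )
        best = min(m.aicc for m in group)
        for m in group:
            m.delta_aicc = m.aicc - best
        fits.extend(group)
    return fits


def suite_report(fits: list[ModelFit], full: bool = False) -> pd.DataFrame:
    """Model-suite table; by default only the interaction coefficient is
    surfaced (reporting every adjusted coefficient invites the 'table 2'
    misreading of confounder effects as causal)."""
    rows = []
    for m in fits:
        row = {
            "response": m.response, "predictor": m.predictor,
            "family": m.family, "interaction": m.interaction,
            "k": m.k, "aicc": m.aicc, "delta_aicc": m.delta_aicc,
        }
        term = m.interaction_term
        if m.interaction and term in m.coefficients.index:
            row["interaction_coef"] = float(m.coefficients[term])
            row["interaction_se"] = float(m.bse[term])
        if full:
            for name, val in m.coefficients.items():
                row[f"coef[{name}]"] = float(val)
        rows.append(row)
    return pd.DataFrame(rows)


def predict_scenarios(
    fit: ModelFit, table: pd.DataFrame, scenarios: dict[str, dict[str, float]]
) -> pd.DataFrame:
    """Predicted response (with 95% interval) at covariate scenarios.

    Unspecified covariates are held at their sample means; Poisson
    predictions are returned on the response (count) scale with
    delta-method intervals.
    """
    means = {
        c: float(table[c].mean())
        for c in (*ADJUSTMENT_TERMS, "pop_density", *PREDICTORS_OF_INTEREST)
        if c in table.columns
    }
    rows = []
    for name, setting in scenarios.items():
        exog = {**means, **setting}
        pred = fit.result.get_prediction(pd.DataFrame([exog]))
        frame = pred.summary_frame(alpha=0.05)
        mean_col = "mean" if "mean" in frame.columns else "predicted_mean"
        lo_col = next(c for c in frame.columns if c.endswith("ci_lower"))
        hi_col = next(c for c in frame.columns if c.endswith("ci_upper"))
        rows.append(
            {
                "scenario": name,
                "predicted": float(frame[mean_col].iloc[0]),
                "ci_lower": float(frame[lo_col].iloc[0]),
                "ci_upper": float(frame[hi_col].iloc[0]),
            }
        )
    return pd.DataFrame(rows)
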