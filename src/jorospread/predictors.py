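"""Climate comparison and correlated-predictor reduction.

Two jobs: (1) compare the climate the species occupies in its native and
introduced ranges, predictor by predictor, with Mann-Whitney U tests and
the rank-biserial effect size; (2) reduce a set of candidate bioclimate
predictors to an uncorrelated, high-performing subset by ranking each
predictor with a bivariate (single-predictor) logistic regression against
presence/background and then iteratively discarding the worst-ranked member
of any highly correlated pair (|Pearson r| above a threshold, default .7)
until no such pair remains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geodata import RasterLayer

logger = logging.getLogger(__name__)

# |r_rb| thresholds for the conventional effect-size classes
_LARGE = 0.5
_MODERATE = 0.3


@dataclass(frozen=True)
class PredictorComparison:
    name: str
    u_statistic: float
    p_value: float
    r_rb: float
    effect_class: str  # small | moderate | large


@dataclass(frozen=True)
class RankedPredictor:
    name: str
    odds_ratio: float
    rank: int  # 1 = best
    flagged: bool = False


def classify_effect(r_rb: float) -> str:
    a = abs(r_rb)
    if a > _LARGE:
        return "large"
    if a > _MODERATE:
        return "moderate"
    return "small"


def mann_whitney_rankbiserial(
    x: np.ndarray, y: np.ndarray, name: str = ""
) -> PredictorComparison:
    """Mann-Whitney U with midrank ties and the rank-biserial effect size.

    ``r_rb = 1 - 2U_x/(n_x n_y)`` where ``U_x`` counts (with midrank tie
    credit) how often an x value exceeds a y value; +1 means x stochastically
    larger. The p-value is the two-sided tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    u_x = float(res.statistic)
    r_rb = 1.0 - 2.0 * u_x / (x.size * y.size)
    return PredictorComparison(
        name=name,
        u_statistic=u_x,
        p_value=float(res.pvalue),
        r_rb=r_rb,
        effect_class=classify_effect(r_rb),
    )


def compare_climates(
    native: pd.DataFrame, introduced: pd.DataFrame, predictors: list[str] | None = None
) -> pd.DataFrame:
    """Per-predictor native-vs-introduced comparison table."""
    predictors = predictors or [
        c for c in native.columns if c in introduced.columns
        and pd.api.types.is_numeric_dtype(native[c])
    ]
    rows = []
    for p in predictors:
        c = mann_whitney_rankbiserial(
            native[p].dropna().to_numpy(), introduced[p].dropna().to_numpy(), name=p
        )
        rows.append(
            {"predictor": p, "U": c.u_statistic, "p_value": c.p_value,
             "r_rb": c.r_rb, "effect": c.effect_class}
        )
    return pd.DataFrame(rows)


def _bivariate_slope(x: np.ndarray, y01: np.ndarray) -> tuple[float, bool, bool]:
    """Slope of logit(P(presence)) ~ x; returns (slope, converged, separated)."""
    import warnings

    import statsmodels.api as sm

    X = sm.add_constant(x)
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation is handled below
            fit = sm.Logit(y01, X).fit(disp=False, maxiter=200)
        slope = float(fit.params[1])
        converged = bool(fit.mle_retvals.get("converged", True))
        # complete separation drives |slope| out and deviance to ~0
        separated = (not converged or not np.isfinite(slope)) and (
            abs(slope) > 10 or not np.isfinite(slope)
        )
        return slope, converged, separated
    except Exception as exc:  # PerfectSeparationError and friends
        separated = "separat" in str(exc).lower()
        return (np.inf, False, True) if separated else (0.0, False, False)


def rank_predictors(samples: pd.DataFrame, label_col: str = "label") -> list[RankedPredictor]:
    """Rank predictors by single-predictor logistic regressions.

    Each predictor is standardized (mean 0, sd 1) and fit alone against the
    presence/background label; predictors are ranked by descending
    |log odds ratio| (i.e. |slope| on the standardized scale). A perfectly
    separating predictor is maximally informative: it is flagged and ranked
    best. Any other non-convergent fit is flagged and ranked worst.
    """
    predictors = [
        c for c in samples.columns
        if c not in (label_col, "lon", "lat")
        and pd.api.types.is_numeric_dtype(samples[c])
    ]
    y = (samples[label_col] == "presence").to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both presence and background labels are required")
    entries = []  # (sort_key, name, odds_ratio, flagged); larger key = better
    for i, p in enumerate(predictors):
        x = samples[p].to_numpy(dtype=float)
        sd = x.std(ddof=0)
        if sd == 0:
            entries.append((0.0, i, p, 1.0, True))
            continue
        z = (x - x.mean()) / sd
        slope, converged, separated = _bivariate_slope(z, y)
        if separated:
            entries.append((np.inf, i, p, np.inf, True))
        elif not converged:
            entries.append((-np.inf, i, p, float(np.exp(slope)), True))
        else:
            entries.append((abs(slope), i, p, float(np.exp(slope)), False))
    # descending |log OR|; ties broken by earlier column order
    entries.sort(key=lambda e: (-e[0], e[1]))
    return [
        RankedPredictor(name=p, odds_ratio=orat, rank=r + 1, flagged=fl)
        for r, (_, _, p, orat, fl) in enumerate(entries)
    ]


def correlated_pairs(values: pd.DataFrame, names: list[str], r_threshold: float = 0.7
                     ) -> list[tuple[str, str, float]]:
    """All pairs among ``names`` with |Pearson r| > threshold."""
    corr = values[names].corr(method="pearson")
    out = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            r = float(corr.loc[a, b])
            if abs(r) > r_threshold:
                out.append((a, b, r))
    return out


def reduce_predictors(
    ranks: list[RankedPredictor],
    values: pd.DataFrame,
    r_threshold: float = 0.7,
) -> list[str]:
    """Iteratively drop the worst-ranked member of any highly correlated pair.

    One removal per pass: recompute all pairwise correlations among the
    survivors, flag pairs with |r| > threshold, remove the single
    worst-ranked predictor that participates in at least one flagged pair,
    repeat until no flagged pair remains. Survivors return in rank order.
    """
    rank_of = {rp.name: rp.rank for rp in ranks}
    surviving = sorted(rank_of, key=rank_of.get)
    missing = [p for p in surviving if p not in values.columns]
    if missing:
        raise ValueError(f"ranked predictors absent from values table: {missing}")
    while True:
        flagged = correlated_pairs(values, surviving, r_threshold)
        if not flagged:
            return surviving
        involved = {n for a, b, _ in flagged for n in (a, b)}
        worst = max(involved, key=rank_of.get)
        logger.info("reduce_predictors: removing %s (rank %d)", worst, rank_of[worst])
        surviving = [p for p in surviving if p != worst]


def max_wind_speed(monthly_wind: list[RasterLayer], name: str = "wind_speed_max"
                   ) -> RasterLayer:
    """Cell-wise maximum over the 12 monthly wind-speed layers.

    Peak (not mean) wind is the biologically relevant stress on orb webs and
    on ballooning dispersal. Nodata in any month propagates to the output.
    """
    if len(monthly_wind) != 12:
        raise ValueError(f"expected 12 monthly layers, got {len(monthly_wind)}")
    first = monthly_wind[0]
    for lay in monthly_wind[1:]:
        if not lay.same_grid(first):
            raise ValueError(f"layer '{lay.name}' geometry mismatch")
    stack = np.stack([lay.values for lay in monthly_wind])
    # plain max: NaN in any month propagates, as required
    return RasterLayer(
        name=name, x_min=first.x_min, y_min=first.y_min, cell=first.cell,
        values=np.max(stack, axis=0), nodata=first.nodata,
    )
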