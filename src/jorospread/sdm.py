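"""Presence-background SDM ensemble with spatial-block cross-validation.

Four model families are fit to presence vs background points on
standardized predictors and later averaged cell-wise:

* ``glm`` — binomial regression with linear + quadratic terms;
* ``gam`` — binomial fit with a penalized B-spline smooth per predictor;
* ``maxent_like`` — the penalized-logistic formulation of maximum entropy
  modelling, with linear, quadratic and hinge feature expansions and an L1
  penalty that shrinks with presence count;
* ``downsampled_rf`` — a classification forest whose per-tree bootstrap
  draws equal presence and background counts (down-sampling), sqrt(p)
  candidate predictors per split.

Because occurrence data are spatially autocorrelated, random CV folds leak
information between train and test; folds are therefore assigned to square
spatial blocks (default edge 860 km) randomly dealt into k folds, so a
held-out fold is geographically disjoint from its training data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .geodata import KM_PER_DEG, RasterLayer

logger = logging.getLogger(__name__)

MODEL_KINDS = ("glm", "gam", "maxent_like", "downsampled_rf")


@dataclass(frozen=True)
class StandardizationParams:
    """Training-table means/sds, reused verbatim at projection time."""

    means: dict[str, float]
    sds: dict[str, float]

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for name, mu in self.means.items():
            out[name] = (out[name] - mu) / self.sds[name]
        return out

    def inverse(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for name, mu in self.means.items():
            out[name] = out[name] * self.sds[name] + mu
        return out


def standardize(
    table: pd.DataFrame, predictors: list[str] | None = None
) -> tuple[pd.DataFrame, StandardizationParams]:
    """Center and scale each predictor column to mean 0, sd 1."""
    predictors = predictors or [
        c for c in table.columns
        if c not in ("lon", "lat", "label") and pd.api.types.is_numeric_dtype(table[c])
    ]
    if len(table) < 2:
        raise ValueError("need at least 2 rows to standardize")
    means, sds = {}, {}
    for c in predictors:
        mu = float(table[c].mean())
        sd = float(table[c].std(ddof=1))  # sample sd, as R scale() does
        if sd == 0:
            raise ValueError(f"predictor '{c}' is constant (sd = 0)")
        means[c], sds[c] = mu, sd
    params = StandardizationParams(means=means, sds=sds)
    return params.transform(table), params


@dataclass
class SDMConfig:
    min_presences: int = 30
    rf_trees: int = 1000
    rf_sampsize: int | None = None  # per class; default = n presences
    gam_df: int = 6
    gam_alpha: float = 1.0
    maxent_features: tuple[str, ...] = ("linear", "quadratic", "hinge")
    maxent_n_hinges: int = 8
    maxent_c: float | None = None  # default: sqrt(n presences)
    glm_terms: str = "linear+quadratic"  # or "linear"


@dataclass
class FittedSDM:
    """A fitted presence-background model exposing predict() in [0, 1]."""

    model_kind: str
    predictors: list[str]
    _predict: Callable[[pd.DataFrame], np.ndarray] = field(repr=False)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        p = np.asarray(self._predict(table[self.predictors]), dtype=float)
        return np.clip(p, 0.0, 1.0)


def _design_poly(X: np.ndarray, quadratic: bool) -> np.ndarray:
    cols = [np.ones(len(X)), X]
    if quadratic:
        cols.append(X**2)
    return np.column_stack([np.atleast_2d(c.T).T for c in cols])


def _fit_glm(X: np.ndarray, y: np.ndarray, quadratic: bool):
    import statsmodels.api as sm

    D = _design_poly(X, quadratic)
    fit = sm.GLM(y, D, family=sm.families.Binomial()).fit()

    def predict(Z: np.ndarray) -> np.ndarray:
        return fit.predict(_design_poly(Z, quadratic))

    return predict


def _fit_gam(X: np.ndarray, y: np.ndarray, df: int, alpha: float):
    import statsmodels.api as sm
    from statsmodels.gam.api import BSplines, GLMGam

    p = X.shape[1]
    smoother = BSplines(X, df=[df] * p, degree=[3] * p, include_intercept=False)
    exog = np.ones((len(X), 1))
    model = GLMGam(y, exog=exog, smoother=smoother, alpha=[alpha] * p,
                   family=sm.families.Binomial())
    fit = model.fit()

    def predict(Z: np.ndarray) -> np.ndarray:
        # clip to the training span: B-spline bases are undefined outside it
        Zc = np.clip(Z, X.min(axis=0), X.max(axis=0))
        return fit.predict(np.ones((len(Zc), 1)), exog_smooth=Zc)

    return predict


class _HingeExpansion:
    """Linear/quadratic/hinge feature map in the maximum-entropy style.

    Hinge features max(0, (x-k)/(xmax-k)) and max(0, (k-x)/(k-xmin)) at
    training-quantile knots let a linear model express thresholded,
    saturating responses — the expansion that makes the penalized logistic
    model equivalent to default-style Maxent.
    """

    def __init__(self, X: np.ndarray, features: tuple[str, ...], n_hinges: int):
        self.features = features
        self.lo = X.min(axis=0)
        self.hi = X.max(axis=0)
        self.knots = None
        if "hinge" in features and n_hinges > 0:
            qs = np.linspace(0, 1, n_hinges + 2)[1:-1]
            self.knots = np.quantile(X, qs, axis=0)  # (n_hinges, p)

    def __call__(self, Z: np.ndarray) -> np.ndarray:
        cols = []
        if "linear" in self.features:
            cols.append(Z)
        if "quadratic" in self.features:
            cols.append(Z**2)
        if self.knots is not None:
            for j in range(Z.shape[1]):
                lo, hi = self.lo[j], self.hi[j]
                for k in self.knots[:, j]:
                    if hi > k:
                        cols.append(np.maximum(0.0, (Z[:, j] - k) / (hi - k))[:, None])
                    if k > lo:
                        cols.append(np.maximum(0.0, (k - Z[:, j]) / (k - lo))[:, None])
        return np.hstack(cols)


def _fit_maxent(X: np.ndarray, y: np.ndarray, cfg: SDMConfig, seed: int):
    from sklearn.linear_model import LogisticRegression

    expand = _HingeExpansion(X, cfg.maxent_features, cfg.maxent_n_hinges)
    F = expand(X)
    n_pres = int(y.sum())
    C = cfg.maxent_c if cfg.maxent_c is not None else float(np.sqrt(n_pres))
    if np.isinf(C):
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
    else:
        clf = LogisticRegression(C=C, l1_ratio=1.0, solver="liblinear",
                                 random_state=seed, max_iter=2000)
    clf.fit(F, y)

    def predict(Z: np.ndarray) -> np.ndarray:
        return clf.predict_proba(expand(Z))[:, 1]

    return predict


class _BalancedForest:
    """Forest of full trees, each on a balanced bootstrap of the two classes."""

    def __init__(self, n_trees: int, sampsize: int | None, seed: int):
        self.n_trees = n_trees
        self.sampsize = sampsize
        self.seed = seed
        self.trees = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_BalancedForest":
        from sklearn.tree import DecisionTreeClassifier

        rng = np.random.default_rng(self.seed)
        idx_pos = np.flatnonzero(y == 1)
        idx_neg = np.flatnonzero(y == 0)
        m = self.sampsize or len(idx_pos)
        self.trees = []
        for _ in range(self.n_trees):
            boot = np.concatenate([
                rng.choice(idx_pos, size=m, replace=True),
                rng.choice(idx_neg, size=m, replace=True),
            ])
            tree = DecisionTreeClassifier(
                max_features="sqrt",
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(X[boot], y[boot])
            self.trees.append(tree)
        return self

    def predict_proba1(self, Z: np.ndarray) -> np.ndarray:
        votes = np.zeros(len(Z))
        for tree in self.trees:
            proba = tree.predict_proba(Z)
            votes += proba[:, 1] if proba.shape[1] == 2 else tree.classes_[0] * np.ones(len(Z))
        return votes / len(self.trees)


def fit_sdm(
    kind: str,
    table: pd.DataFrame,
    predictors: list[str] | None = None,
    config: SDMConfig | None = None,
    seed: int = 0,
) -> FittedSDM:
    """Fit one presence-background model on a standardized sample table.

    ``table`` must carry a ``label`` column with both 'presence' and
    'background' rows, and one column per (already standardized) predictor.
    """
    cfg = config or SDMConfig()
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind '{kind}'; expected one of {MODEL_KINDS}")
    predictors = predictors or [
        c for c in table.columns
        if c not in ("lon", "lat", "label") and pd.api.types.is_numeric_dtype(table[c])
    ]
    y = (table["label"] == "presence").to_numpy(dtype=float)
    n_pres = int(y.sum())
    if n_pres < cfg.min_presences:
        raise ValueError(f"{n_pres} presences < required minimum {cfg.min_presences}")
    if n_pres == len(y):
        raise ValueError("table has no background rows")
    X = table[predictors].to_numpy(dtype=float)

    if kind == "glm":
        pred = _fit_glm(X, y, quadratic=(cfg.glm_terms == "linear+quadratic"))
    elif kind == "gam":
        pred = _fit_gam(X, y, df=cfg.gam_df, alpha=cfg.gam_alpha)
    elif kind == "maxent_like":
        pred = _fit_maxent(X, y, cfg, seed)
    else:
        forest = _BalancedForest(cfg.rf_trees, cfg.rf_sampsize, seed).fit(X, y)
        pred = forest.predict_proba1

    def _predict(df: pd.DataFrame) -> np.ndarray:
        return pred(df.to_numpy(dtype=float))

    return FittedSDM(model_kind=kind, predictors=predictors, _predict=_predict)


def assign_spatial_blocks(
    table: pd.DataFrame,
    block_size_km: float = 860.0,
    k: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Deal square spatial blocks randomly into k folds; one fold per point.

    Degrees are converted to km at the dataset mid-latitude, blocks tile the
    point bounding box, and whole blocks are shuffled and dealt round-robin
    so every fold receives blocks. Returns fold ids 1..k per row.
    """
    if block_size_km <= 0:
        raise ValueError("block size must be > 0")
    if k < 2:
        raise ValueError("k must be >= 2")
    lon = table["lon"].to_numpy(dtype=float)
    lat = table["lat"].to_numpy(dtype=float)
    mid_lat = float(np.mean(lat))
    x = lon * KM_PER_DEG * np.cos(np.radians(mid_lat))
    y = lat * KM_PER_DEG
    bx = np.floor((x - x.min()) / block_size_km).astype(int)
    by = np.floor((y - y.min()) / block_size_km).astype(int)
    block_ids = bx * 100003 + by
    uniq = np.unique(block_ids)
    if len(uniq) < k:
        raise ValueError(
            f"only {len(uniq)} non-empty spatial blocks for k={k} folds"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    fold_of_block = {uniq[j]: (i % k) + 1 for i, j in enumerate(order)}
    return np.array([fold_of_block[b] for b in block_ids])


def auc_rank(pres_scores: np.ndarray, bg_scores: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney rank statistic (midrank ties)."""
    from scipy.stats import rankdata

    n1, n0 = len(pres_scores), len(bg_scores)
    ranks = rankdata(np.concatenate([pres_scores, bg_scores]))
    r1 = ranks[:n1].sum()
    return float((r1 - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass(frozen=True)
class BlockCVResult:
    fold_id: int
    auc: float
    mae: float


def cross_validate(
    kind: str,
    table: pd.DataFrame,
    folds: np.ndarray,
    predictors: list[str] | None = None,
    config: SDMConfig | None = None,
    seed: int = 0,
) -> tuple[list[BlockCVResult], float, float]:
    """Per-fold held-out AUC and MAE; returns (folds, mean AUC, mean MAE).

    MAE is the mean absolute difference between the predicted probability
    and the 0/1 background/presence label of the held-out points. A fold
    whose held-out part has a single class is skipped and logged.
    """
    folds = np.asarray(folds)
    results = []
    for f in np.unique(folds):
        test = folds == f
        y_test = (table.loc[test, "label"] == "presence").to_numpy(dtype=float)
        if y_test.min() == y_test.max():
            logger.warning("fold %s held-out part has a single class; skipped", f)
            continue
        model = fit_sdm(kind, table.loc[~test], predictors, config, seed)
        p = model.predict(table.loc[test])
        results.append(
            BlockCVResult(
                fold_id=int(f),
                auc=auc_rank(p[y_test == 1], p[y_test == 0]),
                mae=float(np.mean(np.abs(y_test - p))),
            )
        )
    if not results:
        raise ValueError("no usable folds")
    mean_auc = float(np.mean([r.auc for r in results]))
    mean_mae = float(np.mean([r.mae for r in results]))
    return results, mean_auc, mean_mae


def project(
    model: FittedSDM,
    layers: list[RasterLayer],
    params: StandardizationParams,
) -> RasterLayer:
    """Project a fitted model onto co-registered predictor rasters.

    Target-region cell values pass through the *training-time*
    standardization before prediction; nodata in any layer propagates.
    """
    by_name = {lay.name: lay for lay in layers}
    missing = [p for p in model.predictors if p not in by_name]
    if missing:
        raise ValueError(f"projection layers missing predictors: {missing}")
    first = by_name[model.predictors[0]]
    for p in model.predictors[1:]:
        if not by_name[p].same_grid(first):
            raise ValueError(f"layer '{p}' geometry mismatch")
    stack = np.stack([by_name[p].values for p in model.predictors], axis=-1)
    flat = stack.reshape(-1, len(model.predictors))
    valid = ~np.isnan(flat).any(axis=1)
    out = np.full(len(flat), np.nan)
    if valid.any():
        df = pd.DataFrame(flat[valid], columns=model.predictors)
        out[valid] = model.predict(params.transform(df))
    return RasterLayer(
        name=f"suitability_{model.model_kind}",
        x_min=first.x_min, y_min=first.y_min, cell=first.cell,
        values=out.reshape(first.values.shape), nodata=first.nodata,
    )


def average_models(rasters: list[RasterLayer], name: str = "suitability_mean"
                   ) -> RasterLayer:
    """Equally weighted cell-wise mean; nodata in any input propagates."""
    first = rasters[0]
    for r in rasters[1:]:
        if not r.same_grid(first):
            raise ValueError(f"raster '{r.name}' geometry mismatch")
    stack = np.stack([r.values for r in rasters])
    return RasterLayer(
        name=name, x_min=first.x_min, y_min=first.y_min, cell=first.cell,
        values=np.mean(stack, axis=0), nodata=first.nodata,
    )
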