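"""Regression machinery: design matrices, OLS, adjusted-R2 variance
partitioning, residual-difference mapping and regional prediction summaries.

Three models are compared for each diversity response: an environment model
(climate principal components with quadratics, elevation with a quadratic,
elevation range, log landmass area), an isolation model (a second-order
trend surface over the three phylobetadiversity NMDS axes), and a global
model concatenating both.  Variance is partitioned with adjusted R2:

    unique_iso = adjR2_global - adjR2_env
    unique_env = adjR2_global - adjR2_iso
    shared     = adjR2_env + adjR2_iso - adjR2_global

Fractions can be slightly negative (a standard property of this partition)
and are reported as-is.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ordination import OrdinationResult

__all__ = [
    "DesignMatrix",
    "ModelFit",
    "VariancePartition",
    "validate_env_table",
    "climate_pca",
    "build_env_design",
    "build_isolation_design",
    "build_realm_design",
    "ols_fit",
    "variance_partition",
    "residual_difference",
    "prediction_summary",
    "delta_adjr2",
]

ENV_META_COLUMNS = ("mean_elevation", "elevation_range", "landmass_area")


def validate_env_table(env: pd.DataFrame) -> list[str]:
    """Check required metadata columns; return the climate variable names."""
    for col in ENV_META_COLUMNS:
        if col not in env.columns:
            raise ValueError(f"environment table missing column {col!r}")
    if (env["landmass_area"] <= 0).any():
        raise ValueError("landmass_area must be positive")
    climate = [c for c in env.columns if c not in ENV_META_COLUMNS]
    if env[climate + list(ENV_META_COLUMNS)].isna().any().any():
        raise ValueError("missing values in environment table")
    return climate


@dataclass
class DesignMatrix:
    """Named predictor columns aligned to cell ids (intercept added at fit)."""

    ids: list[str]
    data: pd.DataFrame
    intercept: bool = True

    def __post_init__(self) -> None:
        if list(self.data.index) != list(self.ids):
            self.data = self.data.loc[self.ids]

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def subset(self, ids: Sequence[str]) -> "DesignMatrix":
        return DesignMatrix(list(ids), self.data.loc[list(ids)], self.intercept)

    def concat(self, other: "DesignMatrix") -> "DesignMatrix":
        if list(self.ids) != list(other.ids):
            raise ValueError("cell ids differ between designs")
        return DesignMatrix(self.ids, pd.concat([self.data, other.data], axis=1),
                            self.intercept or other.intercept)


def climate_pca(env: pd.DataFrame, sqrt_vars: Iterable[str] = (),
                n_components: int = 4) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """PCA of the climate variables on the correlation scale.

    Variables named in ``sqrt_vars`` (typically skewed precipitation-like
    columns) are square-root transformed first; all variables are then
    standardized and the correlation matrix eigendecomposed.  Component
    signs are fixed by making each component's largest-magnitude loading
    positive.

    Returns
    -------
    scores : DataFrame (cells x PC1..PCn)
    proportion : ndarray, variance proportion per retained component
    loadings : DataFrame (variables x components)
    """
    climate = validate_env_table(env)
    if len(climate) < n_components:
        raise ValueError(f"only {len(climate)} climate variables for "
                         f"{n_components} components")
    if len(env) <= len(climate):
        raise ValueError("need more cells than climate variables")
    X = env[climate].to_numpy(dtype=float).copy()
    for name in sqrt_vars:
        if name not in climate:
            raise ValueError(f"sqrt variable {name!r} not a climate column")
        j = climate.index(name)
        if np.any(X[:, j] < 0):
            raise ValueError(f"negative values in sqrt variable {name!r}")
        X[:, j] = np.sqrt(X[:, j])
    sd = X.std(axis=0, ddof=1)
    for j, s in enumerate(sd):
        if s == 0:
            raise ValueError(f"constant climate variable {climate[j]!r}")
    Z = (X - X.mean(axis=0)) / sd
    corr = (Z.T @ Z) / (len(env) - 1)
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    vals, vecs = np.maximum(vals[order], 0.0), vecs[:, order]
    for j in range(n_components):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    scores = Z @ vecs[:, :n_components]
    prop = vals[:n_components] / vals.sum()
    names = [f"PC{i+1}" for i in range(n_components)]
    return (pd.DataFrame(scores, index=env.index, columns=names),
            prop,
            pd.DataFrame(vecs[:, :n_components], index=climate, columns=names))


def build_env_design(env: pd.DataFrame, climate_scores: pd.DataFrame) -> DesignMatrix:
    """Environment predictors: PC1..PC4 + squares, elevation + square,
    elevation range, log landmass area (12 columns)."""
    validate_env_table(env)
    if list(env.index) != list(climate_scores.index):
        raise ValueError("cell ids of env table and climate scores differ")
    cols = {}
    for name in climate_scores.columns:
        cols[name] = climate_scores[name].to_numpy(dtype=float)
    for name in climate_scores.columns:
        cols[f"{name}_sq"] = cols[name] ** 2
    elev = env["mean_elevation"].to_numpy(dtype=float)
    cols["elev"] = elev
    cols["elev_sq"] = elev ** 2
    cols["elev_range"] = env["elevation_range"].to_numpy(dtype=float)
    cols["log_area"] = np.log(env["landmass_area"].to_numpy(dtype=float))
    ids = [str(i) for i in env.index]
    return DesignMatrix(ids, pd.DataFrame(cols, index=ids))


def build_isolation_design(ord_result: OrdinationResult) -> DesignMatrix:
    """Second-order trend surface over the NMDS axes: k linear terms, k
    quadratics, and all pairwise interactions (9 columns for k=3)."""
    X = ord_result.coordinates
    k = X.shape[1]
    if k != 3:
        import warnings
        warnings.warn(f"building generalized second-order surface for k={k} axes")
    cols = {}
    for j in range(k):
        cols[f"nmds{j+1}"] = X[:, j]
    for j in range(k):
        cols[f"nmds{j+1}_sq"] = X[:, j] ** 2
    for a in range(k):
        for b in range(a + 1, k):
            cols[f"nmds{a+1}x{b+1}"] = X[:, a] * X[:, b]
    ids = list(ord_result.ids)
    return DesignMatrix(ids, pd.DataFrame(cols, index=ids))


def build_realm_design(realms: Mapping[str, str] | pd.Series) -> DesignMatrix:
    """Dummy coding of discrete realm labels, alphabetically first label as
    the reference level (r-1 columns)."""
    s = pd.Series(realms).astype(str)
    levels = sorted(s.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 realm labels")
    ids = [str(i) for i in s.index]
    cols = {f"realm_{lev}": (s == lev).astype(float).to_numpy()
            for lev in levels[1:]}
    return DesignMatrix(ids, pd.DataFrame(cols, index=ids))


@dataclass
class ModelFit:
    """OLS fit summary keyed by cell id."""

    coefficients: pd.Series
    fitted: pd.Series
    residuals: pd.Series
    r2: float
    adj_r2: float
    n: int
    p: int


def _collinear_columns(M: np.ndarray, names: list[str]) -> list[str]:
    rank = 0
    bad = []
    acc = np.empty((M.shape[0], 0))
    for j, name in enumerate(names):
        trial = np.hstack([acc, M[:, j:j + 1]])
        r = np.linalg.matrix_rank(trial)
        if r > rank:
            acc, rank = trial, r
        else:
            bad.append(name)
    return bad


def ols_fit(X: DesignMatrix, y: pd.Series) -> ModelFit:
    """Ordinary least squares of ``y`` on the design (plus intercept)."""
    ids = X.ids
    y = y.loc[ids]
    n = len(ids)
    names = X.columns
    M = X.data.to_numpy(dtype=float)
    if X.intercept:
        M = np.hstack([np.ones((n, 1)), M])
        names = ["intercept"] + names
    p = len(X.columns)
    if n <= p + 1:
        raise ValueError(f"n={n} too small for p={p} predictors")
    # scale columns to unit norm for the rank check so that predictors on
    # very different scales (elev^2 vs NMDS axes) are judged fairly
    norms = np.linalg.norm(M, axis=0)
    if np.any(norms == 0):
        zero = [names[j] for j in np.flatnonzero(norms == 0)]
        raise ValueError(f"rank-deficient design; collinear columns: {zero}")
    Mn = M / norms
    if np.linalg.matrix_rank(Mn) < M.shape[1]:
        raise ValueError(f"rank-deficient design; collinear columns: "
                         f"{_collinear_columns(Mn, names)}")
    beta, _, _, _ = np.linalg.lstsq(M, y.to_numpy(dtype=float), rcond=None)
    fitted = M @ beta
    resid = y.to_numpy(dtype=float) - fitted
    yc = y.to_numpy(dtype=float)
    sst = float(np.sum((yc - yc.mean()) ** 2)) if X.intercept else float(np.sum(yc ** 2))
    ssr = float(np.sum(resid ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else 0.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return ModelFit(pd.Series(beta, index=names),
                    pd.Series(fitted, index=ids),
                    pd.Series(resid, index=ids),
                    r2, adj, n, p)


@dataclass
class VariancePartition:
    """Adjusted-R2 decomposition into unique and shared fractions."""

    adj_r2_env: float
    adj_r2_iso: float
    adj_r2_global: float
    unique_iso: float
    unique_env: float
    shared: float

    def as_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in self.__dict__.items()}


def variance_partition(y: pd.Series, X_env: DesignMatrix, X_iso: DesignMatrix,
                       ) -> tuple[VariancePartition, ModelFit, ModelFit, ModelFit]:
    """Fit env-only, isolation-only, and global models; partition adjusted R2.

    Returns the partition and the three fits (env, iso, global).
    """
    if list(X_env.ids) != list(X_iso.ids):
        raise ValueError("designs cover different cells")
    fit_env = ols_fit(X_env, y)
    fit_iso = ols_fit(X_iso, y)
    fit_glob = ols_fit(X_env.concat(X_iso), y)
    part = VariancePartition(
        adj_r2_env=fit_env.adj_r2,
        adj_r2_iso=fit_iso.adj_r2,
        adj_r2_global=fit_glob.adj_r2,
        unique_iso=fit_glob.adj_r2 - fit_env.adj_r2,
        unique_env=fit_glob.adj_r2 - fit_iso.adj_r2,
        shared=fit_env.adj_r2 + fit_iso.adj_r2 - fit_glob.adj_r2,
    )
    return part, fit_env, fit_iso, fit_glob


def residual_difference(fit_env: ModelFit, fit_global: ModelFit) -> pd.Series:
    """|residual of env-only model| - |residual of global model| per cell;
    positive values mean isolation improved the fit for that cell."""
    if list(fit_env.residuals.index) != list(fit_global.residuals.index):
        raise ValueError("fits cover different cells")
    out = fit_env.residuals.abs() - fit_global.residuals.abs()
    out.name = "residual_difference"
    return out


def prediction_summary(fit: ModelFit, y: pd.Series, cells: Sequence[str]) -> dict:
    """Median/range of predictions vs observations over a cell subset.

    ``percent_difference`` is (median_pred - median_obs) / median_pred * 100:
    positive when the model over-predicts the subset.
    """
    cells = list(cells)
    if not cells:
        raise ValueError("empty cell subset")
    pred = fit.fitted.loc[cells].to_numpy(dtype=float)
    obs = y.loc[cells].to_numpy(dtype=float)
    mp, mo = float(np.median(pred)), float(np.median(obs))
    return {
        "n_cells": len(cells),
        "median_predicted": mp,
        "range_predicted": [float(pred.min()), float(pred.max())],
        "median_observed": mo,
        "range_observed": [float(obs.min()), float(obs.max())],
        "percent_difference": (mp - mo) / mp * 100.0 if mp != 0 else float("nan"),
    }


def delta_adjr2(y: pd.Series, base: DesignMatrix, extra: DesignMatrix,
                threshold: float = 0.01) -> tuple[float, bool]:
    """Candidate-variable screen: adjusted-R2 gain of adding ``extra`` to
    ``base``; second element is True when the gain exceeds ``threshold``."""
    fit0 = ols_fit(base, y)
    fit1 = ols_fit(base.concat(extra), y)
    gain = fit1.adj_r2 - fit0.adj_r2
    return gain, gain > threshold
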