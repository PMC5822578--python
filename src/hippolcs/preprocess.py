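"""Pre-model adjustments: score orientation and sex/age residualization.

All cognitive scores are oriented so that higher values mean better
performance (choice reaction time, a latency, is negated).  Every analysis
variable is then adjusted for sex and age in days at its own measurement
occasion (scan age for biomarkers, test age for cognition) by ordinary least
squares on that column's complete cases.

Two residualization conventions are provided.  ``keep_location=True`` (the
pipeline default) centers the *predictors*, i.e. removes only the sex/age
variance components while preserving each column's location — necessary so
that between-wave mean change remains estimable downstream.
``keep_location=False`` is classical residualization (residuals mean-zero and
orthogonal to the raw design).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import calibration as calib

__all__ = ["orient_scores", "residualize", "residualize_table", "SexAgeResidualizer"]

ORIENTATION = dict(calib.COGNITIVE_SIGN)


def orient_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Flip reversed-scored columns so higher always means better.

    Involutive: applying twice restores the original values.  The orientation
    map is recorded in ``table.attrs['orientation']``.
    """
    out = table.copy()
    applied = {}
    for name, sign in ORIENTATION.items():
        if sign >= 0:
            continue
        for w in (2, 3):
            col = f"{name}_w{w}"
            if col in out.columns:
                out[col] = -out[col]
                applied[col] = -1.0
    out.attrs["orientation"] = applied
    return out


def _ols_residuals(y: np.ndarray, X: np.ndarray, keep_location: bool) -> tuple:
    """Complete-case OLS of y on [1, X]; residuals at observed positions.

    Returns (residual vector with NaN preserved, beta, n_used, dropped cols).
    Collinear columns are dropped with a warning.
    """
    obs = np.isfinite(y)
    for j in range(X.shape[1]):
        obs &= np.isfinite(X[:, j])
    n = int(obs.sum())
    if n < 3:
        raise ValueError(f"need >= 3 complete cases, got {n}")
    Xc = X[obs]
    yc = y[obs]
    design = np.column_stack([np.ones(n), Xc])
    keep = [0]
    for j in range(1, design.shape[1]):
        trial = design[:, keep + [j]]
        if np.linalg.matrix_rank(trial) > len(keep):
            keep.append(j)
    dropped = [j - 1 for j in range(1, design.shape[1]) if j not in keep]
    if dropped:
        warnings.warn(f"rank-deficient design; dropped predictor column(s) {dropped}")
    D = design[:, keep]
    beta, *_ = np.linalg.lstsq(D, yc, rcond=None)
    if keep_location:
        # center predictors: remove covariate variance, keep the mean
        Dc = D.copy()
        Dc[:, 1:] = D[:, 1:] - D[:, 1:].mean(axis=0)
        resid = yc - Dc[:, 1:] @ beta[1:]
    else:
        resid = yc - D @ beta
    out = np.full_like(y, np.nan, dtype=float)
    out[obs] = resid
    full_beta = np.full(X.shape[1] + 1, np.nan)
    for pos, j in enumerate(keep):
        full_beta[j] = beta[pos]
    return out, full_beta, n, dropped


def residualize(values, sex, age_days, keep_location: bool = False):
    """Residualize one column on {intercept, sex, age}; missing stays missing.

    The fit uses complete cases for this column only; with the default
    ``keep_location=False`` the residuals are mean-zero and orthogonal to the
    design, and the operation is idempotent.
    """
    y = np.asarray(values, dtype=float)
    X = np.column_stack([np.asarray(sex, dtype=float), np.asarray(age_days, dtype=float)])
    resid, _, _, _ = _ols_residuals(y, X, keep_location=keep_location)
    return resid


class SexAgeResidualizer(BaseEstimator, TransformerMixin):
    """Column-wise sex/age residualization of a cohort table.

    Each measurement column is regressed on sex and the age at its own
    occasion (scan age for biomarkers, test age for cognitive scores), using
    that column's complete cases.  Fitted attributes:

    coefficients_ : DataFrame (column, beta_intercept, beta_sex, beta_age, n)
    columns_ : list of residualized columns

    Parameters
    ----------
    keep_location : bool, default True
        Remove only the sex/age variance components, preserving each column's
        mean (so longitudinal mean change survives).  Set False for classical
        mean-zero residuals.
    """

    BIOMARKER_NAMES = calib.BIOMARKERS

    def __init__(self, keep_location: bool = True):
        self.keep_location = keep_location

    def _age_column(self, col: str) -> str:
        wave = col[-1]
        base = col[:-3]
        kind = "scan" if base in self.BIOMARKER_NAMES else "test"
        return f"age_days_{kind}_w{wave}"

    def _target_columns(self, X: pd.DataFrame) -> list:
        names = list(self.BIOMARKER_NAMES) + list(calib.COGNITIVE_DESCRIPTIVES)
        return [
            f"{n}_w{w}" for n in names for w in (2, 3) if f"{n}_w{w}" in X.columns
        ]

    def fit(self, X: pd.DataFrame, y=None):
        X = X.copy()
        self.columns_ = self._target_columns(X)
        rows = []
        self._betas_ = {}
        for col in self.columns_:
            age = X[self._age_column(col)].to_numpy(dtype=float)
            design = np.column_stack([X["sex"].to_numpy(dtype=float), age])
            yv = X[col].to_numpy(dtype=float)
            _, beta, n, _ = _ols_residuals(yv, design, keep_location=self.keep_location)
            self._betas_[col] = beta
            rows.append(
                {
                    "column": col,
                    "beta_intercept": beta[0],
                    "beta_sex": beta[1],
                    "beta_age": beta[2],
                    "n": n,
                }
            )
        self.coefficients_ = pd.DataFrame(rows).set_index("column")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        for col in self.columns_:
            age = X[self._age_column(col)].to_numpy(dtype=float)
            design = np.column_stack([X["sex"].to_numpy(dtype=float), age])
            yv = X[col].to_numpy(dtype=float)
            resid, _, _, _ = _ols_residuals(yv, design, keep_location=self.keep_location)
            out[col] = resid
        out.attrs = dict(X.attrs)
        out.attrs["residualized"] = {"keep_location": self.keep_location}
        return out


def residualize_table(table: pd.DataFrame, keep_location: bool = True) -> pd.DataFrame:
    """Orient scores, then residualize every measurement column on sex/age.

    The per-column regression coefficients are attached as a DataFrame in
    ``result.attrs['coefficients']``.
    """
    oriented = orient_scores(table)
    res = SexAgeResidualizer(keep_location=keep_location)
    out = res.fit(oriented).transform(oriented)
    out.attrs["coefficients"] = res.coefficients_
    return out
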