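"""Bivariate line fitting: ordinary least squares and standardized major axis.

Allometric studies fit straight lines on linear or log10 scales.  OLS is
used when one variable predicts the other (vertical residuals); SMA when the
two variables stand in a mutual relationship and both carry error, the
standard choice for estimating scaling exponents.  The SMA slope magnitude
is sd(y)/sd(x) with the sign of the Pearson correlation.

Two surfaces are provided: plain functions returning :class:`FitResult`
(``ols_fit``, ``sma_fit``) and scikit-learn style estimators
(:class:`OLSLine`, :class:`SMALine`) that compose with sklearn tooling.

Confidence interval for the SMA slope (the standard allometry-literature
interval, as implemented in the smatr tradition): with
``B = F_{0.95}(1, n-2) * (1 - r^2) / (n - 2)``, the 95 % interval is
``b * (sqrt(B + 1) -/+ sqrt(B))`` for the lower/upper bound (bounds ordered
by value, so a negative slope swaps them).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import (
    DegenerateInputError,
    InsufficientDataError,
    InvalidInputError,
    UndefinedSlopeSignError,
)

__all__ = [
    "FitResult",
    "ols_fit",
    "sma_fit",
    "adjusted_r2",
    "log10_pairs",
    "OLSLine",
    "SMALine",
]


@dataclass(frozen=True)
class FitResult:
    """One fitted line ``y = intercept + slope * x``.

    ``r2`` is the adjusted R² for OLS and the squared Pearson correlation
    for SMA.  ``slope_ci`` is the 95 % confidence interval on the slope and
    ``p_value`` the two-sided test of zero association.
    """

    slope: float
    intercept: float
    r2: float
    n: int
    method: str  # "OLS" | "SMA"
    scale: str  # "linear" | "log10"
    slope_ci: Tuple[float, float]
    p_value: float

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def _as_xy(xs, ys) -> Tuple[np.ndarray, np.ndarray]:
    x = np.asarray(xs, dtype=float).ravel()
    y = np.asarray(ys, dtype=float).ravel()
    if x.shape != y.shape:
        raise InvalidInputError(
            f"x and y must have equal length, got {x.size} and {y.size}"
        )
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InvalidInputError("x and y must be finite")
    if x.size < 3:
        raise InsufficientDataError(f"need at least 3 observations, got {x.size}")
    return x, y


def adjusted_r2(r2_raw: float, n: int) -> float:
    """Adjusted R² for a simple (one-predictor) regression.

    ``1 - (1 - r2) * (n - 1) / (n - 2)``; may be negative for poor fits —
    no clamping is applied.
    """
    if n < 3:
        raise InsufficientDataError(f"adjusted R² needs n >= 3, got {n}")
    if not 0.0 <= r2_raw <= 1.0:
        raise InvalidInputError(f"r2_raw must lie in [0, 1], got {r2_raw}")
    return 1.0 - (1.0 - r2_raw) * (n - 1) / (n - 2)


def log10_pairs(xs, ys) -> Tuple[np.ndarray, np.ndarray]:
    """Elementwise base-10 logarithms of a paired sample.

    Every value must be strictly positive; the error names the first
    offending row index.
    """
    x = np.asarray(xs, dtype=float).ravel()
    y = np.asarray(ys, dtype=float).ravel()
    if x.shape != y.shape:
        raise InvalidInputError(
            f"x and y must have equal length, got {x.size} and {y.size}"
        )
    for name, arr in (("x", x), ("y", y)):
        bad = np.flatnonzero(~(arr > 0.0))
        if bad.size:
            raise InvalidInputError(
                f"{name} must be strictly positive for log10; "
                f"first offending index: {int(bad[0])} (value {arr[bad[0]]!r})"
            )
    return np.log10(x), np.log10(y)


def ols_fit(xs, ys, scale: str = "linear") -> FitResult:
    """Ordinary least squares line of y on x.

    The intercept is always estimated (never forced through the origin) and
    the reported ``r2`` is adjusted for the single predictor.  ``scale`` is
    recorded metadata describing the scale the inputs are on.
    """
    x, y = _as_xy(xs, ys)
    if np.ptp(x) == 0.0:
        raise DegenerateInputError("x has zero variance; OLS slope is undefined")
    res = stats.linregress(x, y)
    n = x.size
    tcrit = stats.t.ppf(0.975, n - 2)
    ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    return FitResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=adjusted_r2(float(res.rvalue) ** 2, n),
        n=n,
        method="OLS",
        scale=scale,
        slope_ci=(float(ci[0]), float(ci[1])),
        p_value=float(res.pvalue),
    )


def sma_fit(xs, ys, scale: str = "linear") -> FitResult:
    """Standardized major axis line of y against x.

    slope = sign(r) * sd(y)/sd(x); intercept = mean(y) - slope * mean(x);
    r2 is the squared Pearson correlation.  See the module docstring for the
    confidence-interval expression.
    """
    x, y = _as_xy(xs, ys)
    sx = float(np.std(x, ddof=1))
    sy = float(np.std(y, ddof=1))
    if sx == 0.0 or sy == 0.0:
        raise DegenerateInputError("zero variance in x or y; SMA slope is undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    if r == 0.0:
        raise UndefinedSlopeSignError(
            "correlation is exactly zero; the SMA slope sign is undefined"
        )
    n = x.size
    slope = float(np.sign(r)) * sy / sx
    intercept = float(np.mean(y)) - slope * float(np.mean(x))
    r2 = r * r
    B = (1.0 - r2) / (n - 2) * stats.f.ppf(0.95, 1, n - 2)
    bounds = (slope * (np.sqrt(B + 1.0) - np.sqrt(B)),
              slope * (np.sqrt(B + 1.0) + np.sqrt(B)))
    if r2 >= 1.0:
        p = 0.0
    else:
        tstat = abs(r) * np.sqrt((n - 2) / (1.0 - r2))
        p = float(2.0 * stats.t.sf(tstat, n - 2))
    return FitResult(
        slope=slope,
        intercept=intercept,
        r2=r2,
        n=n,
        method="SMA",
        scale=scale,
        slope_ci=(float(min(bounds)), float(max(bounds))),
        p_value=p,
    )


class _LineEstimator(RegressorMixin, BaseEstimator):
    """Shared sklearn plumbing for the single-feature line fitters."""

    def __init__(self, scale: str = "linear"):
        self.scale = scale

    def _validate(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        if X.ndim != 2 or X.shape[1] != 1:
            raise InvalidInputError(
                f"expected a single feature column, got shape {X.shape}"
            )
        y = np.asarray(y, dtype=float).ravel()
        if self.scale not in ("linear", "log10"):
            raise InvalidInputError(f"unknown scale {self.scale!r}")
        x = X[:, 0]
        if self.scale == "log10":
            x, y = log10_pairs(x, y)
        return x, y

    def _store(self, result: FitResult) -> "._LineEstimator":
        self.result_ = result
        self.slope_ = result.slope
        self.intercept_ = result.intercept
        self.r2_ = result.r2
        self.n_ = result.n
        self.slope_ci_ = result.slope_ci
        self.p_value_ = result.p_value
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "result_")
        X = np.asarray(X, dtype=float)
        x = X[:, 0] if X.ndim == 2 else X.ravel()
        if self.scale == "log10":
            return 10.0 ** (self.intercept_ + self.slope_ * np.log10(x))
        return self.intercept_ + self.slope_ * x


class OLSLine(_LineEstimator):
    """OLS simple regression as an sklearn estimator.

    With ``scale="log10"`` the fit is performed on log10-transformed x and y
    and :meth:`predict` maps back to the original scale, i.e. the model is
    the power law ``y = 10**intercept_ * x**slope_``.
    """

    def fit(self, X, y):
        x, yt = self._validate(X, y)
        return self._store(ols_fit(x, yt, scale=self.scale))


class SMALine(_LineEstimator):
    """Standardized major axis fit as an sklearn estimator.

    SMA is symmetric in x and y up to inversion: fitting y against x and x
    against y gives reciprocal slopes.  ``predict`` is provided for
    convenience but SMA is not a prediction method; use :class:`OLSLine`
    when the task is to predict y from x.
    """

    def fit(self, X, y):
        x, yt = self._validate(X, y)
        return self._store(sma_fit(x, yt, scale=self.scale))
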