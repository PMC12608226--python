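"""Exponential pigment~VI calibration and its quality metrics.

The calibration curve is y = a * exp(b * x), where y is the pigment
concentration (mg/L) and x the vegetation-index value.  The exponential
form captures the empirically observed saturation of many indices at
high pigment content.  The primary fit is ordinary least squares of
ln(y) on x — closed form, which keeps exhaustive map computation cheap —
with optional iterative refinement in the original space.

Metrics: R^2 = 1 - SS_res/SS_tot in the original space,
RMSE = sqrt(mean((yhat - y)^2)) in mg/L, and RE = the mean absolute
per-sample deviation expressed as a percentage of the mean concentration.
Literal (as-typeset) variants of R^2 and RMSE are available behind
``literal=True`` for auditability; they are not used by the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["ExpModel", "FitMetrics", "fit_exponential", "evaluate_metrics",
           "fit_and_evaluate", "valid_pairs"]

MIN_VALID_PAIRS = 3
_VAR_EPS = 1e-30


@dataclass(frozen=True)
class ExpModel:
    """Fitted exponential calibration y = a * exp(b * x).

    ``a`` is the concentration scale (mg/L, positive); ``b`` the
    dimensionless rate per index unit.
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.a) or self.a <= 0:
            raise ValueError(f"scale a must be positive and finite, got {self.a}")
        if not np.isfinite(self.b):
            raise ValueError(f"rate b must be finite, got {self.b}")

    def predict(self, x) -> np.ndarray:
        with np.errstate(over="ignore"):
            return self.a * np.exp(self.b * np.asarray(x, dtype=float))

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b}


@dataclass(frozen=True)
class FitMetrics:
    """Calibration quality: R^2 (dimensionless), RMSE (mg/L), RE (%), n used."""

    r2: float
    rmse: float
    re_percent: float
    n: int

    def to_dict(self) -> dict:
        return {"r2": self.r2, "rmse": self.rmse,
                "re_percent": self.re_percent, "n": self.n}


def valid_pairs(vi, pigment) -> np.ndarray:
    """Boolean mask of usable (finite VI, positive pigment) pairs."""
    x = np.asarray(vi, dtype=float)
    y = np.asarray(pigment, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vi and pigment must have equal length")
    return np.isfinite(x) & np.isfinite(y) & (y > 0)


def fit_exponential(vi, pigment, *, refine: bool = False) -> ExpModel:
    """Fit y = a*exp(b*x) by least squares of ln(y) on x.

    Pairs with non-finite VI (masked map cells) or non-positive pigment
    are excluded.  Raises ``ValueError`` with fewer than three valid
    pairs or zero variance in the VI values.  With ``refine=True`` the
    log-space solution seeds one Levenberg-Marquardt pass in the
    original space.
    """
    x = np.asarray(vi, dtype=float)
    y = np.asarray(pigment, dtype=float)
    ok = valid_pairs(x, y)
    x, y = x[ok], y[ok]
    if x.size < MIN_VALID_PAIRS:
        raise ValueError(f"need at least {MIN_VALID_PAIRS} valid pairs, got {x.size}")
    xbar = x.mean()
    sxx = np.sum((x - xbar) ** 2)
    if sxx <= _VAR_EPS:
        raise ValueError("zero variance in VI values; calibration undefined")
    z = np.log(y)
    zbar = z.mean()
    b = np.sum((x - xbar) * (z - zbar)) / sxx
    a = np.exp(zbar - b * xbar)
    if refine:
        try:
            (a, b), _ = curve_fit(lambda t, a_, b_: a_ * np.exp(b_ * t),
                                  x, y, p0=(a, b), maxfev=2000)
        except RuntimeError:
            pass  # keep the closed-form solution if refinement stalls
    return ExpModel(float(a), float(b))


def evaluate_metrics(model: ExpModel, vi, pigment, *, literal: bool = False) -> FitMetrics:
    """Compute R^2, RMSE and RE of ``model`` on the given calibration data.

    Uses the same pair-validity rule as the fit.  Raises ``ValueError``
    when the pigment values have zero variance (R^2 undefined).
    """
    x = np.asarray(vi, dtype=float)
    y = np.asarray(pigment, dtype=float)
    ok = valid_pairs(x, y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < MIN_VALID_PAIRS:
        raise ValueError(f"need at least {MIN_VALID_PAIRS} valid pairs, got {n}")
    yhat = model.predict(x)
    ybar = y.mean()
    ss_tot = np.sum((y - ybar) ** 2)
    if ss_tot <= _VAR_EPS:
        raise ValueError("zero variance in pigment values; R^2 undefined")
    if literal:
        r2 = float(np.sum(yhat - ybar) / np.sum(y - ybar)) if np.sum(y - ybar) != 0 else np.nan
        rmse = float(np.sqrt(np.sum((yhat - ybar) ** 2) / n))
    else:
        r2 = float(1.0 - np.sum((y - yhat) ** 2) / ss_tot)
        rmse = float(np.sqrt(np.sum((yhat - y) ** 2) / n))
    re = float(np.mean(np.abs(yhat - y)) * 100.0 / ybar)
    return FitMetrics(r2, rmse, re, int(n))


def fit_and_evaluate(vi, pigment, *, refine: bool = False) -> tuple[ExpModel, FitMetrics]:
    """Convenience: fit then evaluate on the same calibration data (in-sample)."""
    model = fit_exponential(vi, pigment, refine=refine)
    return model, evaluate_metrics(model, vi, pigment)
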