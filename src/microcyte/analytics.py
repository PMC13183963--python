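"""Quantitative layer: agreement/error metrics, linear regression,
exponential growth-rate and doubling time, four-parameter logistic (4PL)
dose-response with IC50, bootstrap sampling plans, and normalisation.

Conventions
-----------
* The 4PL follows the GraphPad parameterisation on a log10-dose axis,
  response(d) = bottom + (top - bottom) / (1 + 10^((log10 d - log10 IC50) * hill)),
  with hill > 0 meaning viability falls as dose rises.
* Growth rate gr comes from ordinary least squares of ln N on t; for two
  timepoints this reduces exactly to gr = ln(Nt/N0)/t, and Td = ln 2 / gr.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .imagesim import DoseResponseTable, GrowthSeries, logistic4

__all__ = [
    "ErrorMetrics", "LinearFit", "DoseResponseFit", "DoublingTimeResult",
    "SamplePlan", "error_metrics", "linear_fit", "doubling_time", "fit_4pl",
    "sample_plan", "normalize_to_max",
]


@dataclass
class ErrorMetrics:
    mae: float
    mse: float
    rmse: float


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r_squared: float


@dataclass
class DoseResponseFit:
    top: float
    bottom: float
    log_ic50: float
    hill_slope: float
    ci_95: tuple          # (lo, hi) on IC50, asymptotic
    r_squared: float
    converged: bool = True

    @property
    def ic50(self) -> float:
        return 10.0 ** self.log_ic50


@dataclass
class DoublingTimeResult:
    gr: float                  # per unit of the series' time axis
    td: float                  # ln2/gr; inf when gr <= 0
    residuals: np.ndarray      # log-scale fit residuals
    nonpositive_growth: bool = False


@dataclass
class SamplePlan:
    n_fields: int
    fraction_of_area: float
    achieved_sd: float
    target_sd: float
    attainable: bool = True


def error_metrics(pred: Sequence[float], truth: Sequence[float]) -> ErrorMetrics:
    """MAE, MSE and RMSE between predictions and reference values."""
    p = np.asarray(pred, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape or p.size == 0:
        raise ValueError("pred and truth must have equal, non-zero length")
    d = p - t
    mse = float(np.mean(d ** 2))
    return ErrorMetrics(float(np.mean(np.abs(d))), mse, math.sqrt(mse))


def linear_fit(x: Sequence[float], y: Sequence[float]) -> LinearFit:
    """OLS line with intercept; R^2 = 1 - SSres/SStot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("at least 3 points are required")
    if np.ptp(x) == 0:
        raise ValueError("x must not be constant")
    res = stats.linregress(x, y)
    pred = res.slope * x + res.intercept
    sstot = float(np.sum((y - y.mean()) ** 2))
    ssres = float(np.sum((y - pred) ** 2))
    r2 = 1.0 - ssres / sstot if sstot > 0 else 0.0
    return LinearFit(float(res.slope), float(res.intercept), r2)


def doubling_time(series: GrowthSeries) -> DoublingTimeResult:
    """Exponential growth rate and doubling time from a growth series.

    gr is the slope of ln N over t (OLS); with exactly two timepoints this
    equals ln(Nt/N0)/(t - t0). Td = ln 2 / gr; a flat or shrinking series
    gets Td = inf with a flag."""
    t = series.timepoints
    n = series.values
    if t.size < 2:
        raise ValueError("at least two timepoints are required")
    logn = np.log(n)
    slope, intercept = np.polyfit(t, logn, 1)
    resid = logn - (slope * t + intercept)
    if slope <= 0:
        return DoublingTimeResult(float(slope), math.inf, resid, True)
    return DoublingTimeResult(float(slope), math.log(2) / slope, resid, False)


def fit_4pl(table: DoseResponseTable, zero_dose_offset: Optional[float] = None,
            n_starts: int = 3) -> DoseResponseFit:
    """Nonlinear least-squares 4PL fit with multi-start initialisation.

    Zero doses are placed on the log axis at `zero_dose_offset` (default:
    the smallest nonzero dose / 10). The 95% CI on IC50 is asymptotic, from
    the Jacobian at the optimum mapped through 10^log_ic50.
    """
    d = table.doses.copy()
    y = table.responses
    nonzero = d[d > 0]
    if nonzero.size == 0:
        raise ValueError("all doses are zero")
    off = zero_dose_offset if zero_dose_offset is not None else nonzero.min() / 10.0
    d[d == 0] = off
    logd = np.log10(d)

    def resid(p):
        top, bottom, lic, hill = p
        return logistic4(10.0 ** logd, top, bottom, lic, hill) - y

    ymax, ymin = float(y.max()), float(y.min())
    mid = 0.5 * (ymax + ymin)
    # dose whose response is closest to the midpoint seeds log IC50
    lic0 = float(logd[np.argmin(np.abs(y - mid))])
    starts = [(ymax, ymin, lic0, hh) for hh in (1.0, 0.5, 2.0)][:max(n_starts, 1)]
    best = None
    for p0 in starts:
        try:
            sol = optimize.least_squares(resid, p0, method="lm", max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return DoseResponseFit(math.nan, math.nan, math.nan, math.nan,
                               (math.nan, math.nan), math.nan, converged=False)
    top, bottom, lic, hill = best.x
    if hill < 0:  # flip to the hill>0 inhibition convention
        top, bottom, hill = bottom, top, -hill
    r = resid((top, bottom, lic, hill))
    sstot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(r ** 2)) / sstot if sstot > 0 else 0.0
    dof = max(y.size - 4, 1)
    s2 = float(np.sum(r ** 2)) / dof
    try:
        cov = np.linalg.inv(best.jac.T @ best.jac) * s2
        se_lic = math.sqrt(max(cov[2, 2], 0.0))
    except np.linalg.LinAlgError:
        se_lic = math.nan
    tcrit = stats.t.ppf(0.975, dof)
    lo, hi = 10.0 ** (lic - tcrit * se_lic), 10.0 ** (lic + tcrit * se_lic)
    return DoseResponseFit(float(top), float(bottom), float(lic), float(hill),
                           (float(lo), float(hi)), r2, converged=best.success)


def sample_plan(field_values: Sequence[float], vessel_area: float,
                field_area: float, target_sd: float = 5.0,
                n_boot: int = 2000, seed: int = 0,
                max_fields: Optional[int] = None) -> SamplePlan:
    """Smallest number of imaged fields whose mean confluency is stable.

    Uses a bootstrap over the observed per-field values: for each n, the SD
    of the mean of n fields resampled with replacement; returns the first n
    below `target_sd` (default 5 percentage points). Reports the fraction
    of the vessel surface those fields cover.
    """
    vals = np.asarray(field_values, dtype=float)
    if vals.size < 10:
        raise ValueError("at least 10 field measurements are required")
    if target_sd <= 0:
        raise ValueError("target_sd must be positive")
    rng = np.random.default_rng(seed)
    max_n = max_fields or vals.size
    if np.ptp(vals) == 0:
        return SamplePlan(1, field_area / vessel_area, 0.0, target_sd, True)
    for n in range(1, max_n + 1):
        boots = rng.choice(vals, size=(n_boot, n), replace=True).mean(axis=1)
        sd = float(boots.std(ddof=1))
        if sd < target_sd:
            return SamplePlan(n, n * field_area / vessel_area, sd, target_sd, True)
    return SamplePlan(max_n, max_n * field_area / vessel_area, sd, target_sd, False)


def normalize_to_max(readouts: Sequence[float]) -> np.ndarray:
    """Express readouts as a percentage of the highest value."""
    v = np.asarray(readouts, dtype=float)
    if v.size == 0 or np.any(v < 0):
        raise ValueError("readouts must be non-negative and non-empty")
    m = v.max()
    if m <= 0:
        raise ValueError("all readouts are zero")
    return 100.0 * v / m
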