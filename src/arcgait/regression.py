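"""Analysis layer: linear landmark-vs-rho fits, Pearson correlation, and
model-vs-measurement agreement.

Goodness of fit is reported as ``R^2 = 1 - RSS/TSS`` of the ordinary
least-squares line (with intercept), so it coincides with the squared
Pearson correlation of the data with the fitted values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ArcGaitError, DomainError
from .model import predict_gait
from .profiles import DEFAULT_CONSTANTS, AnthropometricProfile, ModelConstants

__all__ = [
    "FitResult",
    "linear_fit",
    "pearson_r",
    "bootstrap_slope_ci",
    "model_vs_measurement",
]


@dataclass(frozen=True)
class FitResult:
    """OLS line fit: slope and intercept (landmark units per unit rho,
    landmark units), goodness of fit ``r2``, sample size ``n``, residual
    SD and the slope's standard error."""

    slope: float
    intercept: float
    r2: float
    n: int
    resid_sd: float
    slope_stderr: float

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    def summary(self) -> str:
        return (
            f"y = {self.slope:+.4f} x {self.intercept:+.4f}   "
            f"R^2 = {self.r2:.4f}  (n = {self.n}, resid SD = {self.resid_sd:.4f})"
        )


def _as_1d(a, name):
    a = np.asarray(a, dtype=float)
    if a.ndim != 1:
        raise ArcGaitError(f"{name} must be one-dimensional")
    return a


def linear_fit(x, y) -> FitResult:
    """Ordinary least-squares line of ``y`` on ``x`` with ``R^2 = 1 - RSS/TSS``.

    Requires ``n >= 3`` and non-constant ``x``.  A constant ``y`` has
    zero total sum of squares; by policy its fit reports slope 0 and
    ``R^2 = 0`` with a warning instead of NaN.
    """
    x, y = _as_1d(x, "x"), _as_1d(y, "y")
    if x.size != y.size:
        raise ArcGaitError("x and y differ in length")
    n = x.size
    if n < 3:
        raise ArcGaitError("need at least 3 points for a line fit")
    if np.ptp(x) < 1e-12:
        raise DomainError("constant x: degenerate design")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        warnings.warn("constant y: R^2 reported as 0", stacklevel=2)
        return FitResult(
            slope=0.0, intercept=float(y[0]), r2=0.0, n=n, resid_sd=0.0, slope_stderr=0.0
        )
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    rss = float(np.sum(resid**2))
    r2 = 1.0 - rss / tss
    resid_sd = float(np.sqrt(rss / (n - 2))) if n > 2 else 0.0
    return FitResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=r2,
        n=n,
        resid_sd=resid_sd,
        slope_stderr=float(res.stderr),
    )


def pearson_r(a, b) -> float:
    """Pearson product-moment correlation (requires n >= 3, both varying)."""
    a, b = _as_1d(a, "a"), _as_1d(b, "b")
    if a.size != b.size:
        raise ArcGaitError("inputs differ in length")
    if a.size < 3:
        raise ArcGaitError("need at least 3 points for a correlation")
    if np.ptp(a) < 1e-12 or np.ptp(b) < 1e-12:
        raise DomainError("correlation undefined for a constant input")
    return float(stats.pearsonr(a, b).statistic)


def bootstrap_slope_ci(
    x, y, n_boot: int = 1000, seed: int = 0, level: float = 0.95
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the OLS slope
    (case resampling, vectorized)."""
    x, y = _as_1d(x, "x"), _as_1d(y, "y")
    n = x.size
    if n < 3:
        raise ArcGaitError("need at least 3 points to bootstrap a slope")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    xs, ys = x[idx], y[idx]
    xm = xs.mean(axis=1, keepdims=True)
    ym = ys.mean(axis=1, keepdims=True)
    sxx = np.sum((xs - xm) ** 2, axis=1)
    ok = sxx > 1e-300
    slopes = np.full(n_boot, np.nan)
    slopes[ok] = np.sum((xs - xm) * (ys - ym), axis=1)[ok] / sxx[ok]
    slopes = slopes[np.isfinite(slopes)]
    alpha = (1.0 - level) / 2.0
    return (
        float(np.quantile(slopes, alpha)),
        float(np.quantile(slopes, 1.0 - alpha)),
    )


def model_vs_measurement(
    records,
    profile: AnthropometricProfile,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    measured_dh=None,
):
    """Model predictions vs measured spatiotemporal values, per parameter.

    For every record in the pendular band (1 < rho < 2, non-singular) the
    model's step length, cadence, and gait speed at the record's rho are
    paired with the measured values (step length, 60/duration, step
    length/duration); when a measured COM excursion array is supplied it
    is paired with the model ``dh`` as well.  Returns ``(pairs, r,
    n_excluded)`` — the paired table, the Pearson r per parameter (NaN
    with a warning when a side is constant) and the count of out-of-band
    records excluded.
    """
    rows = []
    n_excluded = 0
    dh_list = []
    for i, rec in enumerate(records):
        if rec.singular or not (1.0 < rec.rho < 2.0):
            n_excluded += 1
            continue
        pred = predict_gait(rec.rho, profile, constants)
        row = {
            "rho": rec.rho,
            "step_length_meas": rec.step_length,
            "step_length_model": pred.step_length,
            "cadence_meas": 60.0 / rec.duration,
            "cadence_model": pred.cadence,
            "speed_meas": rec.step_length / rec.duration,
            "speed_model": pred.speed,
        }
        if measured_dh is not None:
            row["dh_meas"] = float(measured_dh[i])
            row["dh_model"] = pred.com_excursion
        rows.append(row)
    if not rows:
        raise ArcGaitError("no records in the pendular band")
    pairs = pd.DataFrame(rows)
    params = ["step_length", "cadence", "speed"] + (
        ["dh"] if measured_dh is not None else []
    )
    r = {}
    for p in params:
        a, b = pairs[f"{p}_meas"].to_numpy(), pairs[f"{p}_model"].to_numpy()
        try:
            r[p] = pearson_r(a, b)
        except (ArcGaitError, DomainError):
            warnings.warn(f"correlation undefined for {p}", stacklevel=2)
            r[p] = float("nan")
    return pairs, r, n_excluded
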