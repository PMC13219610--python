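"""Scalar evaluators: point accuracy, Theil inequality, interval calibration,
standardized-residual diagnostics, and regression-through-origin external
validation statistics.

Interval-table conventions reconstructed from the reference report:
``calibration_error = nominal - empirical coverage`` and
``sharpness = mean predictive SD = width / (2 * z_{0.975})`` for Gaussian
95% intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from scipy import stats

from .datamodel import PredictionSet, ValidationError

Z975 = float(stats.norm.ppf(0.975))


@dataclass
class PointMetrics:
    rmse: float
    r2: float
    mare: Optional[float]
    mae: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class IntervalMetrics:
    pi: float
    coverage: float
    calibration_error: float
    sharpness: Optional[float]
    nll: Optional[float]
    tic: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ResidualDiagnostics:
    mean: float
    sd: float
    median: float
    skewness: float
    kurtosis: float
    normality_p: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RTOValidation:
    k: float
    k_prime: float
    r2: float
    r0_sq: float
    rel_gap: float

    def to_dict(self) -> dict:
        return asdict(self)


def point_metrics(ps: PredictionSet) -> PointMetrics:
    """RMSE, R^2 (vs. observed mean), MARE and MAE.

    MARE is undefined when any observed value is exactly zero; it is then
    reported as None with a warning and the other metrics are still computed.
    """
    if ps.n < 2:
        raise ValidationError("point metrics require N >= 2")
    err = ps.y - ps.y_hat
    rmse = float(np.sqrt(np.mean(err ** 2)))
    ss_tot = float(np.sum((ps.y - ps.y.mean()) ** 2))
    if ss_tot == 0:
        raise ValidationError("constant observed vector; R2 undefined")
    r2 = 1.0 - float(np.sum(err ** 2)) / ss_tot
    mae = float(np.mean(np.abs(err)))
    if np.any(ps.y == 0):
        warnings.warn("MARE undefined: observed value equal to zero")
        mare = None
    else:
        mare = float(np.mean(np.abs(err / ps.y)))
    return PointMetrics(rmse, r2, mare, mae)


def tic(ps: PredictionSet) -> float:
    """Theil inequality coefficient in [0, 1]; 0 = perfect agreement."""
    num = math.sqrt(float(np.mean((ps.y - ps.y_hat) ** 2)))
    den = math.sqrt(float(np.mean(ps.y ** 2))) + \
        math.sqrt(float(np.mean(ps.y_hat ** 2)))
    if den == 0:
        raise ValidationError("TIC undefined: both vectors all-zero")
    return num / den


def interval_metrics(ps: PredictionSet, nominal: float = 0.95) -> IntervalMetrics:
    """Mean width, empirical coverage, calibration error, sharpness, NLL, TIC."""
    if not ps.has_intervals():
        missing = [f for f in ("lower", "upper") if getattr(ps, f) is None]
        raise ValidationError(f"interval metrics need bounds; missing {missing}")
    width = ps.upper - ps.lower
    pi = float(np.mean(width))
    covered = (ps.y >= ps.lower) & (ps.y <= ps.upper)
    coverage = float(np.mean(covered))
    sharpness = nll = None
    if ps.sigma is not None:
        sharpness = float(np.mean(ps.sigma))
        if np.any(ps.sigma <= 0):
            nll = None
        else:
            nll = float(np.mean(0.5 * np.log(2 * np.pi * ps.sigma ** 2)
                                + (ps.y - ps.y_hat) ** 2 / (2 * ps.sigma ** 2)))
    return IntervalMetrics(pi, coverage, nominal - coverage,
                           sharpness, nll, tic(ps))


def sharpness_from_width(width: float, level: float = 0.95) -> float:
    """Predictive SD implied by a Gaussian central interval of a given mean
    width (width / (2 z) at the 95% level = width / 3.92)."""
    z = stats.norm.ppf(0.5 + level / 2)
    return width / (2 * z)


def residual_diagnostics(ps: PredictionSet,
                         excess_kurtosis: bool = False) -> ResidualDiagnostics:
    """Folded standardized residual statistics, z_i = |y_i - mu_i| / sigma_i.

    Location/shape statistics are computed on the folded values (all means
    and medians positive, as in the reference report); the omnibus
    D'Agostino-Pearson normality test runs on the signed residuals.  Kurtosis
    is raw (non-excess) by default so the folded-normal reference sits near
    3.9; pass ``excess_kurtosis=True`` for the Fisher convention.
    """
    if ps.sigma is None:
        raise ValidationError("residual diagnostics require sigma")
    if np.any(ps.sigma <= 0):
        raise ValidationError("sigma must be strictly positive")
    signed = (ps.y - ps.y_hat) / ps.sigma
    z = np.abs(signed)
    kurt = float(stats.kurtosis(z, fisher=excess_kurtosis, bias=False))
    _, pval = stats.normaltest(signed)
    return ResidualDiagnostics(float(z.mean()), float(z.std(ddof=1)),
                               float(np.median(z)),
                               float(stats.skew(z, bias=False)),
                               kurt, float(pval))


def rto_validation(ps: PredictionSet) -> RTOValidation:
    """Golbraikh-Tropsha style external-validation slopes.

    k is the slope of observed-vs-predicted through the origin, k' the
    reverse.  R0^2 (of several literature conventions) is taken as
    1 - SS(y - k*y_hat) / SS(y - mean(y)): determination of the observed
    values by the origin-constrained line.
    """
    if ps.n < 3:
        raise ValidationError("need N >= 3")
    s_yy = float(np.sum(ps.y ** 2))
    s_hh = float(np.sum(ps.y_hat ** 2))
    if s_yy == 0 or s_hh == 0:
        raise ValidationError("degenerate sums in through-origin regression")
    s_yh = float(np.sum(ps.y * ps.y_hat))
    k = s_yh / s_hh
    k_prime = s_yh / s_yy
    r2 = point_metrics(ps).r2
    ss_tot = float(np.sum((ps.y - ps.y.mean()) ** 2))
    r0 = 1.0 - float(np.sum((ps.y - k * ps.y_hat) ** 2)) / ss_tot
    rel_gap = abs(r2 - r0) / abs(r2) if r2 != 0 else float("inf")
    return RTOValidation(k, k_prime, r2, r0, rel_gap)


def conformal_intervals(y: np.ndarray, y_hat: np.ndarray,
                        residuals: np.ndarray,
                        level: float = 0.95) -> PredictionSet:
    """Split/CV-conformal symmetric intervals for a point predictor.

    ``residuals`` are out-of-fold (y - y_hat) values; the half-width is the
    finite-sample-corrected ``level`` quantile of their absolute values and
    the implied Gaussian-equivalent sigma is half-width / z.
    """
    y_hat = np.asarray(y_hat, dtype=float)
    r = np.sort(np.abs(np.asarray(residuals, dtype=float)))
    m = len(r)
    if m < 5:
        raise ValidationError("need at least 5 residuals for conformal quantile")
    rank = min(m - 1, int(math.ceil((m + 1) * level)) - 1)
    q = float(r[rank])
    sigma = np.full_like(y_hat, sharpness_from_width(2 * q, level))
    return PredictionSet(y, y_hat, y_hat - q, y_hat + q, sigma)


def metrics_report(ps: PredictionSet, nominal: float = 0.95) -> dict:
    """Flat JSON-ready report keyed rmse, r2, mare, mae, pi, tic, coverage,
    calibration_error, sharpness, nll."""
    pm = point_metrics(ps)
    out = {"rmse": pm.rmse, "r2": pm.r2, "mare": pm.mare, "mae": pm.mae,
           "tic": tic(ps)}
    if ps.has_intervals():
        im = interval_metrics(ps, nominal)
        out.update({"pi": im.pi, "coverage": im.coverage,
                    "calibration_error": im.calibration_error,
                    "sharpness": im.sharpness, "nll": im.nll})
    return out
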