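"""Robustness diagnostics: Y-scrambling, applicability-domain assessment, and
uncertainty-distance/error association analysis."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional

import numpy as np
from scipy import stats

from .datamodel import CompoundTable, ValidationError
from .partition import yscramble_labels
from .preprocess import Scaler


@dataclass
class YScrambleReport:
    original_r2: float
    scrambled_r2: list[float]
    scrambled_mean: float
    scrambled_sd: float
    scrambled_max: float
    z: float
    passed: bool

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ADReport:
    centroid: np.ndarray
    distances: np.ndarray
    threshold: float
    in_domain: np.ndarray
    in_domain_fraction: float
    pearson_r_width: Optional[float] = None
    q4_q1_width_ratio: Optional[float] = None

    def to_dict(self) -> dict:
        return {"threshold": self.threshold,
                "in_domain_fraction": self.in_domain_fraction,
                "pearson_r_width": self.pearson_r_width,
                "q4_q1_width_ratio": self.q4_q1_width_ratio,
                "distances": np.asarray(self.distances).tolist(),
                "in_domain": np.asarray(self.in_domain).astype(bool).tolist()}


def _r2(y, y_hat):
    ss = np.sum((y - y_hat) ** 2)
    return 1.0 - ss / np.sum((y - np.mean(y)) ** 2)


def yscrambling(model_factory: Callable, X: np.ndarray, y: np.ndarray,
                n_perm: int = 50, seed: int = 0,
                holdout_fraction: float = 0.2) -> YScrambleReport:
    """Refit under permuted labels with a fixed protocol and compare
    out-of-sample R^2 against the chance distribution.

    ``model_factory(X_train, y_train) -> predict callable``.  One held-out
    split (a fifth of the rows by default, seeded, shared by every
    permutation) scores both the original and the scrambled fits; the test
    passes when the original R^2 exceeds both mean + 2 SD and the maximum of
    the scrambled values.
    """
    if n_perm < 10:
        raise ValidationError("n_perm must be >= 10")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_hold = max(1, int(round(holdout_fraction * n)))
    hold, train = perm[:n_hold], perm[n_hold:]

    predict = model_factory(X[train], y[train])
    original = float(_r2(y[hold], predict(X[hold])))

    scrambled = []
    for i, y_perm in enumerate(yscramble_labels(y, n_perm, seed + 1)):
        try:
            pred_s = model_factory(X[train], y_perm[train])
        except Exception as exc:
            raise ValidationError(
                f"model factory failed on permutation {i}: {exc}") from exc
        scrambled.append(float(_r2(y_perm[hold], pred_s(X[hold]))))

    arr = np.asarray(scrambled)
    mean, sd, mx = float(arr.mean()), float(arr.std(ddof=1)), float(arr.max())
    z = (original - mean) / sd if sd > 0 else float("inf")
    passed = bool(original > mean + 2 * sd and original > mx)
    return YScrambleReport(original, scrambled, mean, sd, mx, float(z), passed)


def ad_assess(train: CompoundTable, query: CompoundTable,
              scaler: Optional[Scaler] = None,
              threshold_rule: str = "mean_2sd",
              widths: Optional[np.ndarray] = None) -> ADReport:
    """Centroid-distance applicability domain in standardized space.

    Default threshold: mean + 2 SD of the training compounds' own distances
    to the training centroid; ``percentile`` uses the 97.5th percentile.
    """
    if train.columns != query.columns:
        raise ValidationError("query columns do not match training columns")
    if scaler is None:
        center = train.X.mean(axis=0)
        scale = train.X.std(axis=0, ddof=1)
        if np.any(scale == 0):
            raise ValidationError("zero-variance training column")
    else:
        if scaler.columns != train.columns:
            raise ValidationError("scaler does not match table columns")
        center, scale = scaler.center, scaler.scale
    Zt = (train.X - center) / scale
    Zq = (query.X - center) / scale
    centroid = Zt.mean(axis=0)
    d_train = np.linalg.norm(Zt - centroid, axis=1)
    d_query = np.linalg.norm(Zq - centroid, axis=1)
    if threshold_rule == "mean_2sd":
        thr = float(d_train.mean() + 2 * d_train.std(ddof=1))
    elif threshold_rule == "percentile":
        thr = float(np.percentile(d_train, 97.5))
    else:
        raise ValidationError(f"unknown threshold rule {threshold_rule!r}")
    flags = d_query <= thr
    report = ADReport(centroid, d_query, thr, flags, float(flags.mean()))
    if widths is not None:
        widths = np.asarray(widths, dtype=float)
        if len(widths) != len(d_query):
            raise ValidationError("widths misaligned with query rows")
        if np.std(widths) > 1e-10 * (1 + np.abs(widths).mean()) \
                and np.std(d_query) > 0:
            report.pearson_r_width = float(stats.pearsonr(d_query, widths)[0])
        report.q4_q1_width_ratio = _quartile_ratio(d_query, widths)
    return report


def _quartile_ratio(by: np.ndarray, values: np.ndarray) -> float:
    """Mean of ``values`` in the top quartile of ``by`` over the bottom one."""
    q1, q3 = np.percentile(by, [25, 75])
    lo = values[by <= q1]
    hi = values[by >= q3]
    return float(hi.mean() / lo.mean())


def uncertainty_associations(distances: np.ndarray, widths: np.ndarray,
                             abs_errors: np.ndarray) -> dict:
    """Pearson r(distance, width) plus quartile-contrast ratios."""
    d = np.asarray(distances, dtype=float)
    w = np.asarray(widths, dtype=float)
    e = np.asarray(abs_errors, dtype=float)
    if not (len(d) == len(w) == len(e)):
        raise ValidationError("misaligned inputs")
    if len(d) < 20:
        raise ValidationError("need N >= 20")
    for name, v in (("distances", d), ("widths", w), ("abs_errors", e)):
        if np.std(v) <= 1e-10 * (1 + np.abs(v).mean()):
            raise ValidationError(f"zero variance in {name}")
    return {
        "pearson_r_distance_width": float(stats.pearsonr(d, w)[0]),
        "q4_q1_width_ratio_by_distance": _quartile_ratio(d, w),
        "q4_q1_error_ratio_by_width": _quartile_ratio(w, e),
    }
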