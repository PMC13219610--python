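"""Descriptor screening chain: variance filter, pairwise-correlation filter,
supervised top-k selection, and leakage-safe z-scoring.

All fitting statistics come from training rows only; test rows are only ever
transformed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datamodel import CompoundTable, DescriptorSpec, ValidationError
from .partition import FoldPlan


@dataclass
class Scaler:
    """Per-column centering/scaling parameters fitted on training rows."""
    columns: list[str]
    center: np.ndarray
    scale: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.center) / self.scale

    def to_dict(self) -> dict:
        return {"columns": self.columns, "center": self.center.tolist(),
                "scale": self.scale.tolist()}


@dataclass
class PreprocessReport:
    dropped_low_variance: list = field(default_factory=list)
    dropped_correlated: list = field(default_factory=list)  # (kept, dropped, r)
    selected: list = field(default_factory=list)            # (name, score)
    scaler: Optional[Scaler] = None

    def validate(self, k: Optional[int] = None) -> None:
        sel = {nm for nm, _ in self.selected}
        dropped = set(self.dropped_low_variance) | \
            {d for _, d, _ in self.dropped_correlated}
        if sel & dropped:
            raise ValidationError("selected and dropped descriptor sets overlap")
        if k is not None and len(self.selected) != k:
            raise ValidationError(f"expected {k} selected descriptors")
        if self.scaler is not None and np.any(self.scaler.scale <= 0):
            raise ValidationError("scaler has non-positive scale")

    def to_json(self) -> str:
        return json.dumps({
            "dropped_low_variance": self.dropped_low_variance,
            "dropped_correlated": [[a, b, float(r)] for a, b, r in
                                   self.dropped_correlated],
            "selected": [[nm, float(s)] for nm, s in self.selected],
            "scaler": self.scaler.to_dict() if self.scaler else None,
        }, indent=2)


def filter_low_variance(table: CompoundTable, tau: float = 1e-8
                        ) -> tuple[CompoundTable, list[str]]:
    """Drop columns whose sample variance is <= tau, preserving order."""
    if tau < 0:
        raise ValidationError("tau must be >= 0")
    variances = table.X.var(axis=0, ddof=1) if table.n > 1 \
        else np.zeros(table.p)
    keep = [s.name for s, v in zip(table.specs, variances) if v > tau]
    dropped = [s.name for s, v in zip(table.specs, variances) if v <= tau]
    if not keep:
        raise ValidationError("variance filter would drop every column")
    return table.select_columns(keep), dropped


def filter_correlated(table: CompoundTable, r_max: float = 0.9
                      ) -> tuple[CompoundTable, list[tuple]]:
    """Greedy scan in column order; of any pair with |Pearson r| > r_max the
    later-indexed column is dropped.  Deterministic given column order."""
    if table.n < 3:
        raise ValidationError("correlation filter requires n >= 3")
    corr = np.corrcoef(table.X, rowvar=False)
    p = table.p
    dropped_pairs = []
    dropped = set()
    for i in range(p):
        if i in dropped:
            continue
        for j in range(i + 1, p):
            if j in dropped:
                continue
            r = corr[i, j]
            if np.isfinite(r) and abs(r) > r_max:
                dropped.add(j)
                dropped_pairs.append((table.specs[i].name,
                                      table.specs[j].name, float(r)))
    keep = [s.name for idx, s in enumerate(table.specs) if idx not in dropped]
    return table.select_columns(keep), dropped_pairs


def rank_select(table: CompoundTable, k: int = 8,
                folds: Optional[FoldPlan] = None) -> PreprocessReport:
    """Supervised top-k selection by |Pearson correlation with y|, averaged
    over the training side of each CV fold.  Ties break by column order."""
    if table.y is None:
        raise ValidationError("rank_select requires a target column")
    if k > table.p:
        raise ValidationError(f"k={k} exceeds available columns p={table.p}")
    if folds is None:
        fold_sets = [np.arange(table.n)]
    else:
        fold_sets = [folds.train_indices(f) for f in range(1, folds.k + 1)]

    per_fold = np.zeros((len(fold_sets), table.p))
    for fi, rows in enumerate(fold_sets):
        Xf, yf = table.X[rows], table.y[rows]
        xm = Xf - Xf.mean(axis=0)
        ym = yf - yf.mean()
        denom = np.sqrt((xm ** 2).sum(axis=0) * (ym ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, (xm * ym[:, None]).sum(axis=0) / denom, 0.0)
        per_fold[fi] = np.abs(r)
    scores = per_fold.mean(axis=0)
    order = np.argsort(-scores, kind="stable")[:k]
    report = PreprocessReport(
        selected=[(table.specs[j].name, float(scores[j])) for j in order])
    report.per_fold_scores = {table.specs[j].name: per_fold[:, j].tolist()
                              for j in range(table.p)}
    report.validate(k)
    return report


def standardize(fit_rows: CompoundTable, apply_rows: CompoundTable
                ) -> tuple[CompoundTable, Scaler]:
    """Z-score ``apply_rows`` with center/scale estimated on ``fit_rows``."""
    if fit_rows.columns != apply_rows.columns:
        raise ValidationError("fit and apply tables have different columns")
    center = fit_rows.X.mean(axis=0)
    scale = fit_rows.X.std(axis=0, ddof=1)
    if np.any(scale == 0):
        bad = fit_rows.columns[int(np.flatnonzero(scale == 0)[0])]
        raise ValidationError(
            f"column {bad} has zero variance in fit rows; apply the variance "
            "filter first")
    scaler = Scaler(list(fit_rows.columns), center, scale)
    Z = scaler.transform(apply_rows.X)
    specs = []
    for s, c, sc in zip(apply_rows.specs, center, scale):
        zs = DescriptorSpec(s.name, "continuous",
                            (s.lower - c) / sc, (s.upper - c) / sc,
                            (s.mode_or_median - c) / sc,
                            (s.mean - c) / sc, s.sd / sc, (s.sd / sc) ** 2,
                            s.kurtosis, s.monotone_direction)
        specs.append(zs)
    out = CompoundTable(apply_rows.ids, Z, specs, apply_rows.y)
    return out, scaler
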