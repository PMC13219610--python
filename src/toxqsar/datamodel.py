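"""Core tabular types and CSV/JSON plumbing.

The whole toolkit moves data around as :class:`CompoundTable` objects:
a matrix of physicochemical descriptors (rows = compounds), an optional
pIGC50 target vector, and per-column :class:`DescriptorSpec` metadata
(kind, bounds, moments, monotone direction).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("toxqsar")

#: canonical descriptor order: discrete counts first, then continuous
DESCRIPTOR_NAMES = ["NRB", "nROH", "nDB", "MW", "A", "LogP", "GATS1p", "B"]

#: toxicologically motivated monotone directions (+1 non-decreasing,
#: -1 non-increasing, 0 unconstrained)
DEFAULT_MONOTONE = {
    "LogP": +1, "MW": +1, "nDB": +1, "nROH": -1,
    "NRB": 0, "A": 0, "GATS1p": 0, "B": 0,
}

ID_COLUMN = "compound_id"
TARGET_NAME = "pIGC50"


class ValidationError(ValueError):
    """Raised when a table or spec fails its structural contract."""


@dataclass
class DescriptorSpec:
    """Per-descriptor metadata: type, bounds, reference moments, constraint."""

    name: str
    kind: str  # "discrete" | "continuous"
    lower: float
    upper: float
    mode_or_median: float
    mean: float
    sd: float
    variance: float
    kurtosis: float
    monotone_direction: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("discrete", "continuous"):
            raise ValidationError(f"{self.name}: kind must be discrete/continuous")
        if not (self.lower <= self.mode_or_median <= self.upper):
            raise ValidationError(
                f"{self.name}: mode/median {self.mode_or_median} outside "
                f"bounds [{self.lower}, {self.upper}]")
        if self.sd < 0:
            raise ValidationError(f"{self.name}: sd must be >= 0")
        if abs(self.variance - self.sd ** 2) > 0.01 * max(1.0, self.variance):
            raise ValidationError(f"{self.name}: variance inconsistent with sd")
        if self.kind == "discrete":
            if self.lower != int(self.lower) or self.upper != int(self.upper):
                raise ValidationError(f"{self.name}: discrete bounds must be integer")
        if self.monotone_direction not in (-1, 0, 1):
            raise ValidationError(f"{self.name}: monotone_direction must be -1/0/+1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DescriptorSpec":
        return cls(**d)


def _binom_p_for_mode(n: int, mode: int) -> float:
    # floor((n+1)p) == mode  <=>  p in [mode/(n+1), (mode+1)/(n+1)); take midpoint
    return (mode + 0.5) / (n + 1)


def _binom_spec(name: str, upper: int, mode: int, direction: int) -> DescriptorSpec:
    p = _binom_p_for_mode(upper, mode)
    mean = upper * p
    var = upper * p * (1 - p)
    kurt = (1 - 6 * p * (1 - p)) / var  # Fisher excess of Binomial(n, p)
    return DescriptorSpec(name, "discrete", 0, upper, mode, mean,
                          math.sqrt(var), var, kurt, direction)


def reference_specs() -> list[DescriptorSpec]:
    """Reference marginal specs for the eight descriptors.

    Discrete counts carry only bounds and a mode in the reference table; their
    moment fields are filled from the mode-matched bounded binomial family the
    generator uses.
    """
    return [
        _binom_spec("NRB", 15, 1, 0),
        _binom_spec("nROH", 3, 0, -1),
        _binom_spec("nDB", 6, 0, +1),
        DescriptorSpec("MW", "continuous", 0.0, 488.59, 146.1, 150.88,
                       49.971, 2497.1, 3.873, +1),
        DescriptorSpec("A", "continuous", 0.0, 1.630, 0.001, 0.222,
                       0.284, 0.080, 1.796, 0),
        DescriptorSpec("LogP", "continuous", -2.585, 7.206, 1.976, 1.981,
                       1.291, 1.666, 0.243, +1),
        DescriptorSpec("GATS1p", "continuous", 0.201, 2.5, 1.043, 1.084,
                       0.391, 0.153, -0.757, 0),
        DescriptorSpec("B", "continuous", 0.0, 2.102, 0.427, 0.462,
                       0.229, 0.052, 4.834, 0),
    ]


def target_spec() -> DescriptorSpec:
    """Reference marginal spec for the pIGC50 response."""
    return DescriptorSpec(TARGET_NAME, "continuous", 0.33, 6.36, 3.25, 3.267,
                          1.051, 1.104, -0.275, 0)


@dataclass
class CompoundTable:
    """Compound ids + descriptor matrix + optional pIGC50 target."""

    ids: np.ndarray                      # (n,) strings
    X: np.ndarray                        # (n, p) floats
    specs: list[DescriptorSpec]
    y: Optional[np.ndarray] = None       # (n,) floats

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValidationError("X must be 2-dimensional")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)
        self.validate()

    # -- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def columns(self) -> list[str]:
        return [s.name for s in self.specs]

    def col(self, name: str) -> np.ndarray:
        return self.X[:, self.col_index(name)]

    def col_index(self, name: str) -> int:
        try:
            return self.columns.index(name)
        except ValueError:
            raise KeyError(f"unknown descriptor column {name!r}") from None

    def validate(self) -> None:
        n, p = self.X.shape
        if len(self.ids) != n:
            raise ValidationError("ids length does not match X rows")
        if len(self.specs) != p:
            raise ValidationError("specs length does not match X columns")
        if len(set(self.ids.tolist())) != n:
            raise ValidationError("duplicate compound ids")
        if np.isnan(self.X).any():
            i, j = np.argwhere(np.isnan(self.X))[0]
            raise ValidationError(
                f"missing value at row {i}, column {self.specs[j].name}")
        if self.y is not None:
            if len(self.y) != n:
                raise ValidationError("y length does not match X rows")
            if np.isnan(self.y).any():
                i = int(np.flatnonzero(np.isnan(self.y))[0])
                raise ValidationError(f"missing target value at row {i}")
        for j, s in enumerate(self.specs):
            if s.kind == "discrete" and n:
                cx = self.X[:, j]
                if not np.allclose(cx, np.round(cx)):
                    raise ValidationError(f"column {s.name}: non-integer values "
                                          "in discrete column")
                if cx.min() < s.lower or cx.max() > s.upper:
                    raise ValidationError(
                        f"column {s.name}: values outside [{s.lower}, {s.upper}]")

    # -- manipulation ---------------------------------------------------
    def subset(self, rows: Sequence[int]) -> "CompoundTable":
        rows = np.asarray(rows, dtype=int)
        return CompoundTable(self.ids[rows], self.X[rows],
                             list(self.specs),
                             None if self.y is None else self.y[rows])

    def select_columns(self, names: Sequence[str]) -> "CompoundTable":
        idx = [self.col_index(nm) for nm in names]
        return CompoundTable(self.ids, self.X[:, idx],
                             [self.specs[i] for i in idx], self.y)

    def with_y(self, y: np.ndarray) -> "CompoundTable":
        return CompoundTable(self.ids, self.X, list(self.specs), y)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.columns)
        df.insert(0, ID_COLUMN, self.ids)
        if self.y is not None:
            df[TARGET_NAME] = self.y
        return df


@dataclass
class PredictionSet:
    """Observed/predicted vectors plus optional interval bounds and SDs."""
    y: np.ndarray
    y_hat: np.ndarray
    lower: Optional[np.ndarray] = None
    upper: Optional[np.ndarray] = None
    sigma: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.y_hat = np.asarray(self.y_hat, dtype=float)
        n = len(self.y)
        if len(self.y_hat) != n:
            raise ValidationError("y and y_hat lengths differ")
        for name in ("lower", "upper", "sigma"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if len(v) != n:
                    raise ValidationError(f"{name} length differs from y")
                setattr(self, name, v)
        if self.lower is not None and self.upper is not None:
            if np.any(self.lower > self.y_hat + 1e-9) or \
               np.any(self.upper < self.y_hat - 1e-9):
                raise ValidationError("interval bounds do not bracket y_hat")
        if self.sigma is not None and np.any(self.sigma < 0):
            raise ValidationError("sigma must be >= 0")

    @property
    def n(self) -> int:
        return len(self.y)

    def has_intervals(self) -> bool:
        return self.lower is not None and self.upper is not None


def _infer_specs(df: pd.DataFrame) -> list[DescriptorSpec]:
    specs = []
    for name in df.columns:
        x = df[name].to_numpy(dtype=float)
        if len(x) == 0:
            specs.append(DescriptorSpec(name, "continuous", 0.0, 1.0, 0.5,
                                        0.5, 0.0, 0.0, 0.0,
                                        DEFAULT_MONOTONE.get(name, 0)))
            continue
        is_int = np.allclose(x, np.round(x))
        kind = "discrete" if is_int else "continuous"
        lo = float(np.floor(x.min())) if is_int else float(x.min())
        hi = float(np.ceil(x.max())) if is_int else float(x.max())
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        kurt = float(stats.kurtosis(x, fisher=True, bias=False)) if len(x) > 3 else 0.0
        specs.append(DescriptorSpec(
            name, kind, lo, hi, float(np.median(x)), float(np.mean(x)),
            sd, sd ** 2, kurt, DEFAULT_MONOTONE.get(name, 0)))
    return specs


def read_table(path, target_column: Optional[str] = TARGET_NAME,
               specs: Optional[list[DescriptorSpec]] = None) -> CompoundTable:
    """Read a descriptor CSV into a validated :class:`CompoundTable`.

    Exact duplicate rows sharing a compound id are collapsed to the first
    occurrence (count logged); the same id with conflicting descriptor values
    is an error.  Missing or non-numeric cells are a hard error naming the
    offending row and column.
    """
    df = pd.read_csv(path, dtype={0: str})
    if df.columns[0] != ID_COLUMN:
        raise ValidationError(f"first column must be {ID_COLUMN!r}, "
                              f"got {df.columns[0]!r}")
    body = df.iloc[:, 1:].copy()
    for cname in body.columns:
        col = pd.to_numeric(body[cname], errors="coerce")
        bad = col.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(f"missing or non-numeric value at row {row}, "
                                  f"column {cname}")
        body[cname] = col

    ids = df[ID_COLUMN].to_numpy(dtype=object)
    dup_mask = pd.Series(ids).duplicated().to_numpy()
    n_dups = int(dup_mask.sum())
    if n_dups:
        full = pd.concat([df[[ID_COLUMN]], body], axis=1)
        # conflicting duplicates (same id, different values) are not collapsible
        nunique = full.groupby(ID_COLUMN, sort=False).nunique()
        if (nunique > 1).any().any():
            bad_id = nunique.index[(nunique > 1).any(axis=1)][0]
            raise ValidationError(
                f"duplicate id {bad_id!r} with conflicting descriptor values")
        logger.info("collapsed %d duplicated row(s) by compound_id", n_dups)
        keep = ~dup_mask
        ids = ids[keep]
        body = body.loc[keep].reset_index(drop=True)

    y = None
    if target_column is not None and target_column in body.columns:
        y = body[target_column].to_numpy(dtype=float)
        body = body.drop(columns=[target_column])

    if specs is None:
        specs = _infer_specs(body)
    return CompoundTable(ids, body.to_numpy(dtype=float), specs, y)


def write_table(table: CompoundTable, path) -> None:
    """Write a table as CSV; round-trips through :func:`read_table` exactly
    (values serialized to 12 significant digits)."""
    table.to_frame().to_csv(path, index=False, float_format="%.12g")


def summarize(table: CompoundTable) -> dict[str, dict[str, float]]:
    """Per-column summary (min, max, mean, sd, variance, median, kurtosis).

    Kurtosis is Fisher excess with sample bias correction; sd/variance use
    the n-1 denominator.
    """
    if table.n < 2:
        raise ValidationError("summarize requires n >= 2 (sd undefined)")
    out = {}
    cols = list(table.columns)
    mat = [table.X[:, j] for j in range(table.p)]
    if table.y is not None:
        cols.append(TARGET_NAME)
        mat.append(table.y)
    for name, x in zip(cols, mat):
        sd = float(np.std(x, ddof=1))
        out[name] = {
            "min": float(np.min(x)),
            "max": float(np.max(x)),
            "mean": float(np.mean(x)),
            "sd": sd,
            "variance": sd ** 2,
            "median": float(np.median(x)),
            "kurtosis": float(stats.kurtosis(x, fisher=True, bias=False))
            if table.n > 3 else float("nan"),
        }
    return out


def write_summary(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)
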