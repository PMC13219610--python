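"""Gradient-boosted regression trees with per-feature monotonicity enforced
during split search (PC-GBM).

Squared-error boosting with exact greedy splits (no histogram binning — the
target workloads are ~2000 x 8, so exactness is affordable and reproducible).
The constraint mechanism is bound-interval propagation: every node carries a
[lo, hi] admissible interval for its leaf values; a split on a +1-constrained
feature is only admissible when the (regularized, clipped) left child value
does not exceed the right child value, and the children inherit tightened
intervals around the midpoint.  Each tree is therefore monotone by
construction, and so is the ensemble sum.

Leaf values are XGBoost-style regularized means: soft-threshold(sum residual,
l1) / (count + l2), clipped to the node's admissible interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .datamodel import ValidationError

_MIN_GAIN = 1e-12


@dataclass
class GBMConfig:
    max_depth: int = 6
    learning_rate: float = 0.05
    n_estimators: int = 300
    subsample: float = 0.8
    l1: float = 0.2
    l2: float = 0.75
    min_samples_leaf: int = 5
    constraints: dict = field(default_factory=dict)  # name -> {-1, 0, +1}
    seed: int = 0

    def to_dict(self) -> dict:
        return {"max_depth": self.max_depth,
                "learning_rate": self.learning_rate,
                "n_estimators": self.n_estimators,
                "subsample": self.subsample, "l1": self.l1, "l2": self.l2,
                "min_samples_leaf": self.min_samples_leaf,
                "constraints": dict(self.constraints), "seed": self.seed}


class _Tree:
    """Flat-array regression tree (feature < 0 marks a leaf)."""

    __slots__ = ("feature", "threshold", "left", "right", "value")

    def __init__(self):
        self.feature: list[int] = []
        self.threshold: list[float] = []
        self.left: list[int] = []
        self.right: list[int] = []
        self.value: list[float] = []

    def add_node(self) -> int:
        self.feature.append(-1)
        self.threshold.append(0.0)
        self.left.append(-1)
        self.right.append(-1)
        self.value.append(0.0)
        return len(self.feature) - 1

    def finalize(self):
        self.feature = np.asarray(self.feature, dtype=int)
        self.threshold = np.asarray(self.threshold, dtype=float)
        self.left = np.asarray(self.left, dtype=int)
        self.right = np.asarray(self.right, dtype=int)
        self.value = np.asarray(self.value, dtype=float)

    def predict(self, X: np.ndarray) -> np.ndarray:
        node = np.zeros(X.shape[0], dtype=int)
        internal = self.feature[node] >= 0
        while internal.any():
            idx = np.flatnonzero(internal)
            nd = node[idx]
            go_left = X[idx, self.feature[nd]] <= self.threshold[nd]
            node[idx] = np.where(go_left, self.left[nd], self.right[nd])
            internal = self.feature[node] >= 0
        return self.value[node]


def _soft_threshold(g: np.ndarray, l1: float) -> np.ndarray:
    return np.sign(g) * np.maximum(np.abs(g) - l1, 0.0)


def _leaf_value(sum_r, count, l1, l2):
    return _soft_threshold(np.asarray(sum_r, dtype=float), l1) / (count + l2)


def _leaf_score(w, sum_r, count, l1, l2):
    # objective improvement of predicting w in the leaf (up to constants)
    return sum_r * w - 0.5 * (count + l2) * w * w - l1 * np.abs(w)


@dataclass
class GBMModel:
    config: GBMConfig
    columns: list[str]
    base_score: float = 0.0
    trees: list = field(default_factory=list)
    gain: Optional[np.ndarray] = None
    fitted: bool = False

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise ValidationError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.columns):
            raise ValidationError(
                f"expected {len(self.columns)} columns, got {X.shape}")
        out = np.full(X.shape[0], self.base_score)
        for tree in self.trees:
            out += self.config.learning_rate * tree.predict(X)
        return out

    def importance(self) -> dict[str, float]:
        """Total split gain per feature, normalized to sum to 1."""
        if not self.fitted:
            raise ValidationError("model is not fitted")
        total = self.gain.sum()
        if total <= 0:
            shares = np.full(len(self.columns), 1.0 / len(self.columns))
        else:
            shares = self.gain / total
        return {c: float(s) for c, s in zip(self.columns, shares)}

    # -- serialization --------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "config": self.config.to_dict(),
            "columns": self.columns,
            "base_score": self.base_score,
            "gain": self.gain.tolist(),
            "trees": [{"feature": t.feature.tolist(),
                       "threshold": t.threshold.tolist(),
                       "left": t.left.tolist(), "right": t.right.tolist(),
                       "value": t.value.tolist()} for t in self.trees],
        })

    @classmethod
    def from_json(cls, s: str) -> "GBMModel":
        d = json.loads(s)
        model = cls(GBMConfig(**d["config"]), d["columns"],
                    d["base_score"], [], np.asarray(d["gain"]), True)
        for td in d["trees"]:
            t = _Tree()
            t.feature = np.asarray(td["feature"], dtype=int)
            t.threshold = np.asarray(td["threshold"], dtype=float)
            t.left = np.asarray(td["left"], dtype=int)
            t.right = np.asarray(td["right"], dtype=int)
            t.value = np.asarray(td["value"], dtype=float)
            model.trees.append(t)
        return model


def _best_split(X, r, rows, cons, lo, hi, cfg):
    """Best admissible split for one node.

    Returns (gain, feature, threshold, left_rows, right_rows, w_l, w_r) or
    None when no admissible split improves the objective.
    """
    m = len(rows)
    msl = cfg.min_samples_leaf
    if m < 2 * msl:
        return None
    Xs = X[rows]
    rs = r[rows]
    sum_all = rs.sum()
    w_parent = float(np.clip(_leaf_value(sum_all, m, cfg.l1, cfg.l2), lo, hi))
    score_parent = _leaf_score(w_parent, sum_all, m, cfg.l1, cfg.l2)

    best = None
    best_gain = _MIN_GAIN
    for j in range(X.shape[1]):
        xj = Xs[:, j]
        order = np.argsort(xj, kind="stable")
        xo = xj[order]
        ro = rs[order]
        csum = np.cumsum(ro)
        k = np.arange(msl, m - msl + 1)  # left counts
        if len(k) == 0:
            continue
        valid = xo[k - 1] < xo[k]
        if not valid.any():
            continue
        k = k[valid]
        sl = csum[k - 1]
        sr = sum_all - sl
        nl = k
        nr = m - k
        wl = np.clip(_leaf_value(sl, nl, cfg.l1, cfg.l2), lo, hi)
        wr = np.clip(_leaf_value(sr, nr, cfg.l1, cfg.l2), lo, hi)
        cj = cons[j]
        if cj > 0:
            ok = wl <= wr
        elif cj < 0:
            ok = wl >= wr
        else:
            ok = np.ones(len(k), dtype=bool)
        if not ok.any():
            continue
        gain = (_leaf_score(wl, sl, nl, cfg.l1, cfg.l2)
                + _leaf_score(wr, sr, nr, cfg.l1, cfg.l2) - score_parent)
        gain = np.where(ok, gain, -np.inf)
        gi = int(np.argmax(gain))
        if gain[gi] > best_gain:
            best_gain = float(gain[gi])
            kk = int(k[gi])
            thr = 0.5 * (xo[kk - 1] + xo[kk])
            best = (best_gain, j, thr, rows[order[:kk]], rows[order[kk:]],
                    float(wl[gi]), float(wr[gi]))
    return best


def _grow_tree(X, r, rows, cons, cfg, gain_acc):
    tree = _Tree()

    def build(rows, depth, lo, hi):
        node = tree.add_node()
        split = None
        if depth < cfg.max_depth:
            split = _best_split(X, r, rows, cons, lo, hi, cfg)
        if split is None:
            sum_r = r[rows].sum()
            w = float(np.clip(_leaf_value(sum_r, len(rows), cfg.l1, cfg.l2),
                              lo, hi))
            tree.value[node] = w
            return node
        gain, j, thr, rows_l, rows_r, wl, wr = split
        gain_acc[j] += gain
        tree.feature[node] = j
        tree.threshold[node] = thr
        if cons[j] > 0:
            mid = 0.5 * (wl + wr)
            lo_l, hi_l, lo_r, hi_r = lo, min(hi, mid), max(lo, mid), hi
        elif cons[j] < 0:
            mid = 0.5 * (wl + wr)
            lo_l, hi_l, lo_r, hi_r = max(lo, mid), hi, lo, min(hi, mid)
        else:
            lo_l = lo_r = lo
            hi_l = hi_r = hi
        tree.left[node] = build(rows_l, depth + 1, lo_l, hi_l)
        tree.right[node] = build(rows_r, depth + 1, lo_r, hi_r)
        return node

    build(np.asarray(rows, dtype=int), 0, -np.inf, np.inf)
    tree.finalize()
    return tree


def fit(X: np.ndarray, y: np.ndarray, config: GBMConfig,
        columns: Optional[list[str]] = None) -> GBMModel:
    """Fit the constrained boosting ensemble."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 10:
        raise ValidationError("fit requires n >= 10")
    if columns is None:
        columns = [f"x{j}" for j in range(p)]
    cons = np.zeros(p, dtype=int)
    for name, d in config.constraints.items():
        if name not in columns:
            raise ValidationError(f"constraint on unknown column {name!r}")
        if d not in (-1, 0, 1):
            raise ValidationError("constraint direction must be -1/0/+1")
        cons[columns.index(name)] = d

    rng = np.random.default_rng(config.seed)
    base = float(y.mean())
    pred = np.full(n, base)
    trees = []
    gain_acc = np.zeros(p)
    m_sub = max(2 * config.min_samples_leaf,
                int(round(config.subsample * n)))
    for _ in range(config.n_estimators):
        rows = (rng.choice(n, size=m_sub, replace=False)
                if m_sub < n else np.arange(n))
        resid = y - pred
        tree = _grow_tree(X, resid, rows, cons, config, gain_acc)
        trees.append(tree)
        pred += config.learning_rate * tree.predict(X)

    return GBMModel(config, list(columns), base, trees, gain_acc, True)


def predict(model: GBMModel, X: np.ndarray) -> np.ndarray:
    return model.predict(X)


def importance(model: GBMModel) -> dict[str, float]:
    return model.importance()


def average_importance(models: list[GBMModel]) -> dict[str, dict[str, float]]:
    """Cross-fold mean/SD of gain shares for stability displays."""
    cols = models[0].columns
    mat = np.array([[m.importance()[c] for c in cols] for m in models])
    return {c: {"mean": float(mat[:, i].mean()), "sd": float(mat[:, i].std(ddof=1))
                if len(models) > 1 else 0.0}
            for i, c in enumerate(cols)}


def check_monotonic(model: GBMModel, anchors: np.ndarray, feature: str,
                    grid_size: int = 21, tol: float = 1e-9,
                    value_range: Optional[tuple] = None) -> int:
    """Count adjacent-pair direction violations on per-anchor sweeps.

    Each anchor row is swept over ``grid_size`` equally spaced values of
    ``feature`` (spanning the anchors' observed range unless ``value_range``
    is given) with all other coordinates fixed.
    """
    if feature not in model.config.constraints or \
            model.config.constraints[feature] == 0:
        raise ValidationError(
            f"{feature!r} is not constrained; use the sensitivity module for "
            "unconstrained response curves")
    direction = model.config.constraints[feature]
    anchors = np.asarray(anchors, dtype=float)
    j = model.columns.index(feature)
    if value_range is None:
        lo, hi = anchors[:, j].min(), anchors[:, j].max()
    else:
        lo, hi = value_range
    if grid_size < 2:
        return 0
    grid = np.linspace(lo, hi, grid_size)
    n_anchors = anchors.shape[0]
    sweep = np.repeat(anchors, grid_size, axis=0)
    sweep[:, j] = np.tile(grid, n_anchors)
    pred = model.predict(sweep).reshape(n_anchors, grid_size)
    diffs = np.diff(pred, axis=1) * direction
    return int(np.sum(diffs < -tol))
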