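"""Seeded surrogate-based hyperparameter search over bounded spaces.

A Gaussian-process surrogate with expected-improvement acquisition proposes
configurations after an initial random stage; every evaluation minimizes a
composite accuracy-reliability loss

    L = RMSE + lambda1 * max(0, nominal - coverage) + lambda2 * PI

averaged over CV folds, so tuned models trade point error against interval
behavior rather than accuracy alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
import warnings

from .datamodel import ValidationError
from .metrics import IntervalMetrics, PointMetrics


@dataclass
class SearchSpace:
    """Hyperparameter bounds: name -> (low, high, kind) with kind in
    {"int", "float", "logfloat"}."""
    params: dict

    def __post_init__(self) -> None:
        for name, (lo, hi, kind) in self.params.items():
            if not lo < hi:
                raise ValidationError(f"{name}: bounds must satisfy low < high")
            if kind not in ("int", "float", "logfloat"):
                raise ValidationError(f"{name}: unknown kind {kind}")

    @property
    def names(self) -> list[str]:
        return list(self.params)

    def decode(self, u: np.ndarray) -> dict:
        """Map a unit-cube point to a config dict."""
        cfg = {}
        for ui, (name, (lo, hi, kind)) in zip(u, self.params.items()):
            if kind == "logfloat":
                v = math.exp(math.log(lo) + ui * (math.log(hi) - math.log(lo)))
            else:
                v = lo + ui * (hi - lo)
            if kind == "int":
                v = int(round(v))
                v = min(max(v, int(lo)), int(hi))
            cfg[name] = v
        return cfg


def gbm_search_space() -> SearchSpace:
    return SearchSpace({
        "max_depth": (5, 7, "int"),
        "learning_rate": (0.03, 0.06, "float"),
        "n_estimators": (250, 400, "int"),
        "subsample": (0.7, 0.9, "float"),
        "l1": (0.1, 0.3, "float"),
        "l2": (0.5, 1.0, "float"),
    })


def bnn_search_space() -> SearchSpace:
    return SearchSpace({
        "learn_rate": (3e-4, 3e-3, "logfloat"),
        "patience": (50, 300, "int"),
        "mc_samples": (50, 400, "int"),
    })


@dataclass
class TuneResult:
    best_config: dict
    best_loss: float
    history: list = field(default_factory=list)  # (config, loss)
    seed: int = 0

    def to_dict(self) -> dict:
        return {"best_config": self.best_config, "best_loss": self.best_loss,
                "history": [{"config": c, "loss": l} for c, l in self.history],
                "seed": self.seed}


def composite_loss(point: PointMetrics, interval: Optional[IntervalMetrics],
                   lambda1: float = 1.0, lambda2: float = 0.5,
                   nominal: float = 0.95) -> float:
    """Accuracy-reliability composite; the coverage term is a one-sided hinge
    (no reward for over-coverage beyond the width penalty)."""
    if lambda1 < 0 or lambda2 < 0:
        raise ValidationError("penalty weights must be >= 0")
    loss = point.rmse
    if interval is not None:
        loss += lambda1 * max(0.0, nominal - interval.coverage)
        loss += lambda2 * interval.pi
    return loss


def optimize(objective: Callable[[dict], float], space: SearchSpace,
             budget: int, seed: int = 0, n_initial: Optional[int] = None,
             n_candidates: int = 512) -> TuneResult:
    """Sequential model-based minimization of ``objective`` over ``space``.

    Random exploration for the first ``n_initial`` evaluations, then a
    Matern-5/2 GP surrogate proposes the expected-improvement maximizer among
    seeded random candidates.  Failed evaluations score +inf and the search
    continues.  Fully deterministic per (seed, budget, space).
    """
    if budget < 5:
        raise ValidationError("budget must be >= 5")
    rng = np.random.default_rng(seed)
    d = len(space.names)
    if n_initial is None:
        n_initial = max(4, min(10, budget // 3))

    U: list[np.ndarray] = []
    losses: list[float] = []
    history = []

    def evaluate(u):
        cfg = space.decode(u)
        try:
            loss = float(objective(cfg))
        except Exception:
            loss = math.inf
        U.append(u)
        losses.append(loss)
        history.append((cfg, loss))

    for _ in range(min(n_initial, budget)):
        evaluate(rng.random(d))

    kernel = Matern(nu=2.5, length_scale=np.full(d, 0.3),
                    length_scale_bounds=(1e-2, 1e2))
    while len(history) < budget:
        finite = np.isfinite(losses)
        if finite.sum() < 2:
            evaluate(rng.random(d))
            continue
        Xf = np.asarray(U)[finite]
        yf = np.asarray(losses)[finite]
        y_mean, y_sd = yf.mean(), yf.std()
        yn = (yf - y_mean) / (y_sd if y_sd > 0 else 1.0)
        gp = GaussianProcessRegressor(kernel=kernel, alpha=1e-6,
                                      normalize_y=False,
                                      random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(Xf, yn)
        cand = rng.random((n_candidates, d))
        mu, sd = gp.predict(cand, return_std=True)
        best_n = yn.min()
        sd = np.maximum(sd, 1e-12)
        imp = best_n - mu
        zsc = imp / sd
        ei = imp * stats.norm.cdf(zsc) + sd * stats.norm.pdf(zsc)
        evaluate(cand[int(np.argmax(ei))])

    best_i = int(np.argmin(losses))
    return TuneResult(history[best_i][0], losses[best_i], history, seed)
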