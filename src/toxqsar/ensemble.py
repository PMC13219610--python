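"""CV-performance-weighted aggregation of member predictions.

Weights are inverse-RMSE (softmax(-RMSE) available as an alternative); the
combined predictive distribution is the weighted Gaussian mixture, so the
ensemble variance includes a member-disagreement term.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .datamodel import PredictionSet, ValidationError


@dataclass
class EnsembleModel:
    member_ids: list[str]
    weights: np.ndarray
    scheme: str = "inverse_rmse"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValidationError("weights must be >= 0 and sum to 1")

    def to_json(self) -> str:
        return json.dumps({"members": self.member_ids,
                           "weights": self.weights.tolist(),
                           "scheme": self.scheme})


def fit_weights(cv_rmse: Sequence[float], member_ids: Sequence[str] = None,
                scheme: str = "inverse_rmse") -> EnsembleModel:
    """Weights from member cross-validation RMSEs."""
    rmse = np.asarray(cv_rmse, dtype=float)
    if np.any(rmse <= 0):
        raise ValidationError("all member RMSEs must be > 0")
    if scheme == "inverse_rmse":
        raw = 1.0 / rmse
    elif scheme == "softmax":
        raw = np.exp(-(rmse - rmse.min()))
    else:
        raise ValidationError(f"unknown weighting scheme {scheme!r}")
    w = raw / raw.sum()
    ids = list(member_ids) if member_ids is not None else \
        [f"m{i}" for i in range(len(rmse))]
    return EnsembleModel(ids, w, scheme)


def predict(members: Sequence[PredictionSet], model: EnsembleModel,
            level: float = 0.95) -> PredictionSet:
    """Mixture aggregation: mu = sum(w*mu_m); var = sum(w*(s^2+mu^2)) - mu^2."""
    if len(members) != len(model.weights):
        raise ValidationError("member count does not match weights")
    n = members[0].n
    for m in members:
        if m.n != n:
            raise ValidationError("member prediction sets are misaligned")
        if m.sigma is None:
            raise ValidationError("every member must supply sigma")
        if not np.array_equal(m.y, members[0].y, equal_nan=True):
            raise ValidationError("members disagree on observed y")
    w = model.weights
    mus = np.stack([m.y_hat for m in members])
    sigmas = np.stack([m.sigma for m in members])
    mu = np.einsum("m,mn->n", w, mus)
    second = np.einsum("m,mn->n", w, sigmas ** 2 + mus ** 2)
    var = np.maximum(second - mu ** 2, 0.0)
    sigma = np.sqrt(var)
    z = stats.norm.ppf(0.5 + level / 2)
    return PredictionSet(members[0].y, mu, mu - z * sigma, mu + z * sigma,
                         sigma)
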