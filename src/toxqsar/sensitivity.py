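"""One-at-a-time descriptor perturbation analysis.

For a set of anchor compounds, each descriptor is swept over its observed
range with every other coordinate held fixed, and the conditional response of
the fitted model is summarized into per-descriptor directional effects, sign
consistency, relative magnitudes, a positive/negative/neutral classification,
and an overall monotonic-consistency percentage against the expected
directions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .datamodel import CompoundTable, ValidationError


@dataclass
class SensitivityReport:
    per_descriptor: dict            # name -> {mean_effect, sign_consistency,
                                    #          relative_magnitude, class}
    n_positive: int
    n_negative: int
    n_neutral: int
    most_positive: str
    most_negative: Optional[str]
    highest_abs_effect: str
    monotonic_consistency_pct: float
    n_anchors: int
    grid_size: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "per_descriptor": self.per_descriptor,
            "total_features_analyzed": len(self.per_descriptor),
            "features_with_positive_effect": self.n_positive,
            "features_with_negative_effect": self.n_negative,
            "features_with_neutral_effect": self.n_neutral,
            "most_positive_effect_feature": self.most_positive,
            "most_negative_effect_feature": self.most_negative,
            "highest_absolute_effect_feature": self.highest_abs_effect,
            "monotonicity_consistency_pct": self.monotonic_consistency_pct,
            "analysis_method": "Perturbation Analysis",
            "samples_used": self.n_anchors,
            "grid_size": self.grid_size,
            "seed": self.seed,
        }


def perturb_feature(predict: Callable, x: np.ndarray, feature_index: int,
                    grid_size: int, value_range: tuple
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Sweep one coordinate of ``x`` over an equally spaced grid; all other
    coordinates stay fixed.  Returns (grid, predictions)."""
    lo, hi = value_range
    if not lo < hi:
        raise ValidationError("need lo < hi")
    if grid_size < 2:
        raise ValidationError("grid_size must be >= 2")
    x = np.asarray(x, dtype=float)
    if feature_index >= len(x):
        raise ValidationError(f"feature index {feature_index} out of range")
    grid = np.linspace(lo, hi, grid_size)
    sweep = np.tile(x, (grid_size, 1))
    sweep[:, feature_index] = grid
    return grid, np.asarray(predict(sweep), dtype=float)


def directional_analysis(predict: Callable, table: CompoundTable,
                         n_anchors: int = 200, grid_size: int = 21,
                         neutral_eps: float = 0.05, seed: int = 0,
                         expected_directions: Optional[dict] = None
                         ) -> SensitivityReport:
    """Per-descriptor directional effect summary over seeded anchors.

    ``expected_directions`` maps descriptor names to +1/-1 for the
    monotonic-consistency statistic; it defaults to the tables' declared
    monotone directions (descriptors with direction 0 are excluded from the
    alignment percentage).  The net effect of a sweep is prediction(hi end)
    minus prediction(lo end); a sweep aligns when the net effect has the
    expected sign (exactly flat counts as aligned for either direction).
    """
    if n_anchors > table.n:
        raise ValidationError(f"n_anchors {n_anchors} exceeds table rows {table.n}")
    if expected_directions is None:
        expected_directions = {s.name: s.monotone_direction
                               for s in table.specs
                               if s.monotone_direction != 0}
    rng = np.random.default_rng(seed)
    anchor_rows = rng.choice(table.n, size=n_anchors, replace=False)
    anchors = table.X[anchor_rows].copy()

    pred_sd = float(np.std(np.asarray(predict(table.X), dtype=float)))
    scale = pred_sd if pred_sd > 0 else 1.0

    effects = {}           # name -> (n_anchors,) net effects
    step_signs = {}        # name -> per-step sign counts
    for j, spec in enumerate(table.specs):
        lo, hi = table.X[:, j].min(), table.X[:, j].max()
        if lo == hi:
            effects[spec.name] = np.zeros(n_anchors)
            step_signs[spec.name] = np.zeros(n_anchors)
            continue
        grid = np.linspace(lo, hi, grid_size)
        sweep = np.repeat(anchors, grid_size, axis=0)
        sweep[:, j] = np.tile(grid, n_anchors)
        pred = np.asarray(predict(sweep), dtype=float).reshape(n_anchors,
                                                               grid_size)
        effects[spec.name] = pred[:, -1] - pred[:, 0]
        steps = np.diff(pred, axis=1)
        step_signs[spec.name] = np.sign(steps)

    per = {}
    aligned = 0
    total_sweeps = 0
    for spec in table.specs:
        eff = effects[spec.name]
        mean_eff = float(eff.mean())
        signs = np.sign(eff)
        nonzero = signs[signs != 0]
        if len(nonzero):
            modal = 1.0 if (nonzero > 0).sum() >= (nonzero < 0).sum() else -1.0
            consistency = float(np.mean(signs == modal))
        else:
            consistency = 1.0
        per[spec.name] = {
            "mean_effect": mean_eff,
            "sign_consistency": consistency,
            "mean_abs_effect": float(np.abs(eff).mean()),
        }
        exp_dir = expected_directions.get(spec.name, 0)
        if exp_dir:
            total_sweeps += len(eff)
            aligned += int(np.sum(eff * exp_dir >= 0))

    max_abs = max(v["mean_abs_effect"] for v in per.values()) or 1.0
    n_pos = n_neg = n_neu = 0
    for name, v in per.items():
        v["relative_magnitude"] = v["mean_abs_effect"] / max_abs
        if abs(v["mean_effect"]) < neutral_eps * scale:
            v["class"] = "neutral"
            n_neu += 1
        elif v["mean_effect"] > 0:
            v["class"] = "positive"
            n_pos += 1
        else:
            v["class"] = "negative"
            n_neg += 1

    most_pos = max(per, key=lambda nm: per[nm]["mean_effect"])
    most_neg = min(per, key=lambda nm: per[nm]["mean_effect"])
    highest = max(per, key=lambda nm: per[nm]["mean_abs_effect"])
    pct = 100.0 * aligned / total_sweeps if total_sweeps else 100.0

    return SensitivityReport(per, n_pos, n_neg, n_neu, most_pos, most_neg,
                             highest, pct, n_anchors, grid_size, seed)
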