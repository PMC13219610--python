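"""Synthetic descriptor/response generator.

Marginals are matched to the reference distribution table (bounds, mean, SD,
mode) and the response surface embeds a planted affine form

    pIGC50 = 0.42*LogP + 0.015*MW - 0.31*GATS1p + 0.05*nDB - 0.05*nROH + C + eps

so monotone ground truth is available for constraint-recovery tests.

Marginal families (the source table states none):
* MW, LogP, GATS1p  -> truncated normal solved to match post-truncation
  mean/SD within bounds;
* A, B              -> truncated lognormal (right-skewed, heavy kurtosis,
  lower bound 0), solved the same way;
* NRB, nROH, nDB    -> bounded binomial with p chosen so the mode matches.

Sampling is inverse-CDF on uniforms, which makes the optional Gaussian-copula
correlation structure a drop-in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .datamodel import (CompoundTable, DescriptorSpec, reference_specs,
                        target_spec, ValidationError)

DEFAULT_COEFFS = {"LogP": 0.42, "MW": 0.015, "GATS1p": -0.31,
                  "nDB": 0.05, "nROH": -0.05}

_CALIBRATION_SEED = 987654321  # internal seed for the post-clip moment solve
_param_cache: dict = {}


class CalibrationError(ValueError):
    """Raised when target moments are infeasible for the chosen coefficients."""


@dataclass
class GeneratorConfig:
    specs: list[DescriptorSpec] = field(default_factory=reference_specs)
    target: DescriptorSpec = field(default_factory=target_spec)
    coeffs: dict = field(default_factory=lambda: dict(DEFAULT_COEFFS))
    intercept: Optional[float] = None
    noise_sd: Optional[float] = None
    copula_correlations: Optional[dict] = None  # {(colA, colB): r}
    seed: int = 0

    def __post_init__(self) -> None:
        names = {s.name: s for s in self.specs}
        for nm, beta in self.coeffs.items():
            if nm not in names:
                raise ValidationError(f"coefficient on unknown descriptor {nm}")
            d = names[nm].monotone_direction
            if d != 0 and beta * d < 0:
                raise ValidationError(
                    f"coefficient sign for {nm} violates its declared "
                    f"monotone direction {d:+d}")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    @property
    def calibrated(self) -> bool:
        return self.intercept is not None and self.noise_sd is not None

    def to_dict(self) -> dict:
        return {
            "specs": [s.to_dict() for s in self.specs],
            "target": self.target.to_dict(),
            "coeffs": dict(self.coeffs),
            "intercept": self.intercept,
            "noise_sd": self.noise_sd,
            "copula_correlations":
                {f"{a}|{b}": r for (a, b), r in self.copula_correlations.items()}
                if self.copula_correlations else None,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        cop = d.get("copula_correlations")
        if cop:
            cop = {tuple(k.split("|")): v for k, v in cop.items()}
        return cls(
            specs=[DescriptorSpec.from_dict(s) for s in d["specs"]],
            target=DescriptorSpec.from_dict(d["target"]),
            coeffs=dict(d["coeffs"]),
            intercept=d.get("intercept"),
            noise_sd=d.get("noise_sd"),
            copula_correlations=cop,
            seed=d.get("seed", 0),
        )


# ---------------------------------------------------------------------------
# marginal families
# ---------------------------------------------------------------------------

def _truncnorm_params(lower, upper, mean, sd):
    """Underlying (mu, sigma) so the [lower, upper]-truncated normal has the
    requested post-truncation mean and SD."""
    key = ("tn", lower, upper, mean, sd)
    if key in _param_cache:
        return _param_cache[key]

    def resid(q):
        mu, log_sigma = q
        sigma = math.exp(log_sigma)
        a, b = (lower - mu) / sigma, (upper - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - mean, math.sqrt(v) - sd]

    sol = optimize.root(resid, [mean, math.log(sd)], method="hybr")
    if not sol.success:  # pragma: no cover - all table rows converge
        raise CalibrationError(f"truncated-normal solve failed: {sol.message}")
    mu, sigma = sol.x[0], math.exp(sol.x[1])
    _param_cache[key] = (mu, sigma)
    return mu, sigma


def _trunclognorm_moments(m, s, lower, upper):
    """Mean and SD of exp(T), T ~ Normal(m, s) truncated to [ln lower, ln upper]."""
    lo = -np.inf if lower <= 0 else (math.log(lower) - m) / s
    hi = (math.log(upper) - m) / s
    z = stats.norm.cdf(hi) - stats.norm.cdf(lo)
    e1 = math.exp(m + 0.5 * s * s) * (
        stats.norm.cdf(hi - s) - stats.norm.cdf(lo - s)) / z
    e2 = math.exp(2 * m + 2 * s * s) * (
        stats.norm.cdf(hi - 2 * s) - stats.norm.cdf(lo - 2 * s)) / z
    var = max(e2 - e1 * e1, 1e-300)
    return e1, math.sqrt(var)


def _trunclognorm_params(lower, upper, mean, sd):
    key = ("tln", lower, upper, mean, sd)
    if key in _param_cache:
        return _param_cache[key]
    cv2 = (sd / mean) ** 2
    s0 = math.sqrt(math.log1p(cv2))
    m0 = math.log(mean) - 0.5 * s0 * s0

    def resid(q):
        m, log_s = q
        s = math.exp(log_s)
        e1, e_sd = _trunclognorm_moments(m, s, lower, upper)
        return [e1 - mean, e_sd - sd]

    sol = optimize.root(resid, [m0, math.log(s0)], method="hybr")
    if not sol.success:  # pragma: no cover
        raise CalibrationError(f"truncated-lognormal solve failed: {sol.message}")
    m, s = sol.x[0], math.exp(sol.x[1])
    _param_cache[key] = (m, s)
    return m, s


def _column_ppf(spec: DescriptorSpec, u: np.ndarray) -> np.ndarray:
    """Inverse CDF of the marginal family chosen for ``spec``."""
    if spec.kind == "discrete":
        n = int(spec.upper)
        p = (spec.mode_or_median + 0.5) / (n + 1)
        return stats.binom.ppf(np.clip(u, 1e-12, 1 - 1e-12), n, p)
    if spec.name in ("A", "B"):
        m, s = _trunclognorm_params(spec.lower, spec.upper, spec.mean, spec.sd)
        lo = -np.inf if spec.lower <= 0 else (math.log(spec.lower) - m) / s
        hi = (math.log(spec.upper) - m) / s
        t = stats.truncnorm.ppf(np.clip(u, 1e-12, 1 - 1e-12), lo, hi,
                                loc=m, scale=s)
        return np.exp(t)
    mu, sigma = _truncnorm_params(spec.lower, spec.upper, spec.mean, spec.sd)
    a, b = (spec.lower - mu) / sigma, (spec.upper - mu) / sigma
    return stats.truncnorm.ppf(np.clip(u, 1e-12, 1 - 1e-12), a, b,
                               loc=mu, scale=sigma)


def _family_moments(spec: DescriptorSpec) -> tuple[float, float]:
    """Mean/SD of the sampling family (equals the spec's targets for the
    continuous solves; binomial moments for discrete columns)."""
    if spec.kind == "discrete":
        n = int(spec.upper)
        p = (spec.mode_or_median + 0.5) / (n + 1)
        return n * p, math.sqrt(n * p * (1 - p))
    return spec.mean, spec.sd


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

def _descriptor_uniforms(config: GeneratorConfig, n: int,
                         rng: np.random.Generator) -> np.ndarray:
    p = len(config.specs)
    if not config.copula_correlations:
        return rng.random((n, p))
    names = [s.name for s in config.specs]
    corr = np.eye(p)
    for (a, b), r in config.copula_correlations.items():
        ia, ib = names.index(a), names.index(b)
        corr[ia, ib] = corr[ib, ia] = r
    # nearest-PD guard: clip tiny negative eigenvalues
    w, v = np.linalg.eigh(corr)
    corr = (v * np.maximum(w, 1e-10)) @ v.T
    d = np.sqrt(np.diag(corr))
    corr = corr / np.outer(d, d)
    z = rng.multivariate_normal(np.zeros(p), corr, size=n,
                                method="cholesky")
    return stats.norm.cdf(z)


def _draw(config: GeneratorConfig, n: int, rng: np.random.Generator):
    u = _descriptor_uniforms(config, n, rng)
    X = np.empty((n, len(config.specs)))
    for j, spec in enumerate(config.specs):
        X[:, j] = _column_ppf(spec, u[:, j])
    return X


def _systematic(config: GeneratorConfig, X: np.ndarray) -> np.ndarray:
    names = [s.name for s in config.specs]
    out = np.zeros(X.shape[0])
    for nm, beta in config.coeffs.items():
        out += beta * X[:, names.index(nm)]
    return out


def calibrate(config: GeneratorConfig, refine: bool = True,
              refine_n: int = 200_000, max_iter: int = 4) -> GeneratorConfig:
    """Solve the intercept and noise SD by moment matching.

    The analytic stage propagates moments under descriptor independence
    (E[y] = sum(beta*mu) + C, Var[y] = sum(beta^2*sigma^2) + noise^2).  With
    ``refine=True`` a fixed-seed simulation then nudges both parameters so the
    *post-clipping* sample mean/SD hit the target moments (the clip at the
    response bounds slightly shrinks the SD).
    """
    tmean, tsd = config.target.mean, config.target.sd
    mean_sys = sum(beta * _family_moments(_spec(config, nm))[0]
                   for nm, beta in config.coeffs.items())
    var_sys = sum((beta * _family_moments(_spec(config, nm))[1]) ** 2
                  for nm, beta in config.coeffs.items())
    noise_var = tsd ** 2 - var_sys
    if noise_var < 0:
        raise CalibrationError(
            f"systematic variance {var_sys:.4f} exceeds target variance "
            f"{tsd ** 2:.4f}; rescale the coefficients")
    C = tmean - mean_sys
    noise_sd = math.sqrt(noise_var)

    if refine:
        rng = np.random.default_rng(_CALIBRATION_SEED)
        X = _draw(config, refine_n, rng)
        sys_part = _systematic(config, X)
        eps = rng.standard_normal(refine_n)
        lo, hi = config.target.lower, config.target.upper
        for _ in range(max_iter):
            y = np.clip(sys_part + C + noise_sd * eps, lo, hi)
            m, s = y.mean(), y.std(ddof=1)
            if abs(m - tmean) < 2e-3 * max(1, abs(tmean)) and \
               abs(s - tsd) < 2e-3 * tsd:
                break
            C += tmean - m
            noise_sd = max(noise_sd * tsd / s, 1e-9)

    out = GeneratorConfig(config.specs, config.target, dict(config.coeffs),
                          float(C), float(noise_sd),
                          config.copula_correlations, config.seed)
    return out


def _spec(config: GeneratorConfig, name: str) -> DescriptorSpec:
    for s in config.specs:
        if s.name == name:
            return s
    raise KeyError(name)


def generate(config: GeneratorConfig, n: int,
             seed: Optional[int] = None) -> CompoundTable:
    """Draw ``n`` synthetic compounds; fully reproducible per seed."""
    if n <= 0:
        raise ValidationError("n must be positive")
    if not config.calibrated:
        raise ValidationError("generator config is not calibrated; "
                              "run calibrate() first")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    X = _draw(config, n, rng)
    y = _systematic(config, X) + config.intercept \
        + config.noise_sd * rng.standard_normal(n)
    y = np.clip(y, config.target.lower, config.target.upper)
    ids = np.array([f"C{i + 1:06d}" for i in range(n)], dtype=object)
    return CompoundTable(ids, X, list(config.specs), y)


def true_response(x, config: GeneratorConfig):
    """Noiseless planted response for a descriptor vector (or matrix) aligned
    to ``config.specs`` order; affine, hence exactly monotone per coefficient
    sign."""
    if not config.calibrated:
        raise ValidationError("generator config is not calibrated")
    x = np.asarray(x, dtype=float)
    one_row = x.ndim == 1
    X = np.atleast_2d(x)
    out = _systematic(config, X) + config.intercept
    return float(out[0]) if one_row else out
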