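"""Metric evaluators, including the brute-force oracle equivalence suite."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from toxqsar.datamodel import PredictionSet, ValidationError
from toxqsar.metrics import (conformal_intervals, interval_metrics,
                             metrics_report, point_metrics,
                             residual_diagnostics, rto_validation,
                             sharpness_from_width, tic)


# -- independent brute-force oracles (scalar loops, no shared code) ---------

def oracle_rmse(y, yh):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(y, yh)) / len(y))


def oracle_r2(y, yh):
    ybar = sum(y) / len(y)
    return 1 - sum((a - b) ** 2 for a, b in zip(y, yh)) / \
        sum((a - ybar) ** 2 for a in y)


def oracle_mare(y, yh):
    return sum(abs((a - b) / a) for a, b in zip(y, yh)) / len(y)


def oracle_mae(y, yh):
    return sum(abs(a - b) for a, b in zip(y, yh)) / len(y)


def oracle_pi(lo, hi):
    return sum(h - l for l, h in zip(lo, hi)) / len(lo)


def oracle_tic(y, yh):
    n = len(y)
    num = math.sqrt(sum((a - b) ** 2 for a, b in zip(y, yh)) / n)
    den = math.sqrt(sum(a * a for a in y) / n) + \
        math.sqrt(sum(b * b for b in yh) / n)
    return num / den


def random_ps(rng, n=30, with_intervals=True):
    y = rng.normal(3, 1, n)
    yh = y + rng.normal(0, 0.5, n)
    if not with_intervals:
        return PredictionSet(y, yh)
    half = rng.uniform(0.2, 1.5, n)
    sigma = half / 1.959963984540054
    return PredictionSet(y, yh, yh - half, yh + half, sigma)


class TestPointMetrics:
    def test_identity(self):
        y = np.array([1.0, 2.0, 3.0])
        pm = point_metrics(PredictionSet(y, y.copy()))
        assert (pm.rmse, pm.r2, pm.mare, pm.mae) == (0, 1, 0, 0)

    def test_hand_arithmetic(self):
        ps = PredictionSet(np.array([1.0, 2, 3]), np.array([1.0, 2, 4]))
        pm = point_metrics(ps)
        assert pm.rmse == pytest.approx(0.5774, abs=1e-4)
        assert pm.r2 == pytest.approx(0.5)
        assert pm.mae == pytest.approx(0.3333, abs=1e-4)
        assert pm.mare == pytest.approx(0.1111, abs=1e-4)

    def test_constant_prediction_r2_zero(self):
        y = np.array([1.0, 2, 3])
        pm = point_metrics(PredictionSet(y, np.full(3, y.mean())))
        assert pm.r2 == pytest.approx(0.0)

    def test_zero_observed_mare_undefined(self):
        ps = PredictionSet(np.array([0.0, 2, 3]), np.array([1.0, 2, 3]))
        with pytest.warns(UserWarning, match="MARE"):
            pm = point_metrics(ps)
        assert pm.mare is None
        assert pm.rmse > 0

    def test_rmse_ge_mae(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            ps = random_ps(rng, with_intervals=False)
            pm = point_metrics(ps)
            assert pm.rmse >= pm.mae - 1e-12


class TestTic:
    def test_identity_zero(self):
        y = np.array([1.0, 2, 3])
        assert tic(PredictionSet(y, y.copy())) == 0

    def test_antipodal_is_one(self):
        y = np.array([1.0, -2, 3])
        assert tic(PredictionSet(y, -y)) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        ps = PredictionSet(np.array([1.0, 2, 3]), np.array([1.0, 2, 4]))
        assert tic(ps) == pytest.approx(0.1201, abs=1e-4)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            tic(PredictionSet(np.zeros(3), np.zeros(3)))

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_always_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(0, 2, 20)
        yh = rng.normal(0, 2, 20)
        if np.all(y == 0) and np.all(yh == 0):
            return
        ps = PredictionSet(y, yh)
        assert 0 <= tic(ps) <= 1


class TestIntervalMetrics:
    def test_reference_calibration_pair_bnn(self):
        # coverage 66.8% at nominal 95% -> calibration error 0.2820
        n = 1000
        y = np.zeros(n)
        covered = np.arange(n) < 668
        yh = np.where(covered, 0.0, 2.0)
        half = np.full(n, 0.5)
        ps = PredictionSet(y, yh, yh - half, yh + half, None)
        im = interval_metrics(ps, nominal=0.95)
        assert im.coverage == pytest.approx(0.668)
        assert im.calibration_error == pytest.approx(0.2820)

    def test_reference_sharpness_pair(self):
        # Gaussian 95% intervals of width 0.4957 -> mean sigma 0.1265
        assert sharpness_from_width(0.4957) == pytest.approx(0.1265,
                                                             abs=2e-4)

    def test_hand_arithmetic(self):
        y = np.array([1.0, 2, 3])
        lo = np.array([0.5, 2.5, 2.5])
        hi = np.array([1.5, 3.5, 3.5])
        yh = (lo + hi) / 2
        im = interval_metrics(PredictionSet(y, yh, lo, hi), nominal=0.95)
        assert im.pi == pytest.approx(1.0)
        assert im.coverage == pytest.approx(2 / 3)
        assert im.calibration_error == pytest.approx(0.2833, abs=1e-4)

    def test_missing_bounds_rejected(self):
        with pytest.raises(ValidationError, match="lower"):
            interval_metrics(PredictionSet(np.ones(3), np.ones(3)))

    def test_calibration_error_linear_in_coverage(self):
        rng = np.random.default_rng(1)
        ps = random_ps(rng, n=200)
        for nominal in (0.8, 0.9, 0.95):
            im = interval_metrics(ps, nominal)
            assert im.calibration_error == pytest.approx(
                nominal - im.coverage)


class TestResidualDiagnostics:
    def test_exact_one_sigma_residuals(self):
        n = 50
        y = np.arange(n, dtype=float)
        sigma = np.full(n, 2.0)
        ps = PredictionSet(y, y - sigma, sigma=sigma)
        rd = residual_diagnostics(ps)
        assert rd.mean == pytest.approx(1.0)
        assert rd.sd == pytest.approx(0.0, abs=1e-12)

    def test_folded_normal_reference(self):
        rng = np.random.default_rng(2)
        n = 10_000
        resid = rng.standard_normal(n)
        y = np.zeros(n)
        ps = PredictionSet(y, resid, sigma=np.ones(n))
        rd = residual_diagnostics(ps)
        # folded standard normal: mean ~0.7979, skew ~0.9953, kurt ~3.87
        assert rd.mean == pytest.approx(0.7979, abs=0.03)
        assert rd.skewness == pytest.approx(0.9953, abs=0.1)
        assert rd.kurtosis == pytest.approx(3.87, abs=0.35)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        ps = random_ps(rng)
        rd1 = residual_diagnostics(ps)
        ps2 = PredictionSet(ps.y, ps.y_hat, sigma=2 * ps.sigma)
        rd2 = residual_diagnostics(ps2)
        assert rd2.mean == pytest.approx(rd1.mean / 2)

    def test_zero_sigma_rejected(self):
        ps = PredictionSet(np.ones(5), np.ones(5), sigma=np.zeros(5))
        with pytest.raises(ValidationError):
            residual_diagnostics(ps)


class TestRTOValidation:
    def test_identity(self):
        y = np.array([1.0, 2, 3])
        rv = rto_validation(PredictionSet(y, y.copy()))
        assert rv.k == pytest.approx(1.0)
        assert rv.k_prime == pytest.approx(1.0)
        assert rv.rel_gap == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic(self):
        ps = PredictionSet(np.array([1.0, 2, 3]),
                           np.array([1.1, 1.9, 3.2]))
        rv = rto_validation(ps)
        assert rv.k == pytest.approx(0.9628, abs=1e-4)
        assert rv.k_prime == pytest.approx(1.0357, abs=1e-4)

    def test_doubling_predictions(self):
        y = np.array([1.0, 2, 3])
        rv = rto_validation(PredictionSet(y, 2 * y))
        assert rv.k == pytest.approx(0.5)
        assert rv.k_prime == pytest.approx(2.0)

    def test_short_input_rejected(self):
        with pytest.raises(ValidationError):
            rto_validation(PredictionSet(np.ones(2), np.ones(2)))


class TestOracleEquivalence:
    def test_thousand_random_prediction_sets(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            n = int(rng.integers(5, 40))
            ps = random_ps(rng, n=n)
            pm = point_metrics(ps)
            y, yh = ps.y.tolist(), ps.y_hat.tolist()
            assert pm.rmse == pytest.approx(oracle_rmse(y, yh), rel=1e-10)
            assert pm.r2 == pytest.approx(oracle_r2(y, yh), rel=1e-10)
            assert pm.mare == pytest.approx(oracle_mare(y, yh), rel=1e-10)
            assert pm.mae == pytest.approx(oracle_mae(y, yh), rel=1e-10)
            assert tic(ps) == pytest.approx(oracle_tic(y, yh), rel=1e-10)
            im = interval_metrics(ps)
            assert im.pi == pytest.approx(
                oracle_pi(ps.lower.tolist(), ps.upper.tolist()), rel=1e-10)


class TestConformal:
    def test_marginal_coverage_on_gaussian_noise(self):
        rng = np.random.default_rng(5)
        y_hat = np.zeros(2000)
        resid_cal = rng.standard_normal(1000)
        y_new = rng.standard_normal(2000)
        ps = conformal_intervals(y_new, y_hat, resid_cal, level=0.9)
        im = interval_metrics(ps, nominal=0.9)
        assert im.coverage == pytest.approx(0.9, abs=0.03)

    def test_report_keys(self):
        rng = np.random.default_rng(6)
        ps = random_ps(rng, n=50)
        rep = metrics_report(ps)
        assert set(rep) == {"rmse", "r2", "mare", "mae", "pi", "tic",
                            "coverage", "calibration_error", "sharpness",
                            "nll"}
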