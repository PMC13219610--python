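import numpy as np
import pytest

from toxqsar import gbm
from toxqsar.datamodel import DEFAULT_MONOTONE, ValidationError
from toxqsar.synthetic import generate, true_response


FAST = dict(n_estimators=80, max_depth=4)


@pytest.fixture(scope="module")
def fitted_constrained(table_large):
    cfg = gbm.GBMConfig(constraints=DEFAULT_MONOTONE, seed=1, **FAST)
    return gbm.fit(table_large.X, table_large.y, cfg,
                   columns=table_large.columns)


@pytest.fixture(scope="module")
def anchors(table_large):
    rng = np.random.default_rng(17)
    return table_large.X[rng.choice(table_large.n, 200, replace=False)]


class TestFit:
    def test_constant_target(self, table_small):
        y = np.full(table_small.n, 2.5)
        m = gbm.fit(table_small.X, y, gbm.GBMConfig(n_estimators=10, seed=0),
                    columns=table_small.columns)
        np.testing.assert_allclose(m.predict(table_small.X), 2.5, atol=1e-9)

    def test_unknown_constraint_column(self, table_small):
        cfg = gbm.GBMConfig(constraints={"bogus": 1}, seed=0)
        with pytest.raises(ValidationError, match="bogus"):
            gbm.fit(table_small.X, table_small.y, cfg,
                    columns=table_small.columns)

    def test_too_few_rows(self):
        with pytest.raises(ValidationError):
            gbm.fit(np.ones((5, 2)), np.ones(5), gbm.GBMConfig())

    def test_generator_r2_above_noise_floor(self, gen_config, table_large,
                                            table_test_split):
        cfg = gbm.GBMConfig(constraints=DEFAULT_MONOTONE, seed=3)
        m = gbm.fit(table_large.X, table_large.y, cfg,
                    columns=table_large.columns)
        pred = m.predict(table_test_split.X)
        r2 = 1 - np.sum((table_test_split.y - pred) ** 2) / \
            np.sum((table_test_split.y - table_test_split.y.mean()) ** 2)
        assert 0.6 <= r2 <= 0.8   # analytic ceiling ~0.79

    def test_unconstrained_equals_zero_constraints(self, table_small):
        cfg0 = gbm.GBMConfig(constraints={}, seed=5, **FAST)
        cfgz = gbm.GBMConfig(constraints={c: 0 for c in table_small.columns},
                             seed=5, **FAST)
        m0 = gbm.fit(table_small.X, table_small.y, cfg0,
                     columns=table_small.columns)
        mz = gbm.fit(table_small.X, table_small.y, cfgz,
                     columns=table_small.columns)
        np.testing.assert_array_equal(m0.predict(table_small.X),
                                      mz.predict(table_small.X))


class TestPredict:
    def test_single_tree_depth_one(self):
        X = np.array([[0.0], [0.0], [1.0], [1.0]] * 5)
        y = np.array([0.0, 0, 1, 1] * 5)
        cfg = gbm.GBMConfig(n_estimators=1, max_depth=1, learning_rate=1.0,
                            subsample=1.0, l1=0.0, l2=0.0,
                            min_samples_leaf=1, seed=0)
        m = gbm.fit(X, y, cfg)
        # base 0.5; leaf values are regularized residual means (+-0.5)
        np.testing.assert_allclose(m.predict(np.array([[0.0], [1.0]])),
                                   [0.0, 1.0], atol=1e-9)

    def test_row_permutation_equivariance(self, fitted_constrained,
                                          table_small):
        perm = np.random.default_rng(0).permutation(table_small.n)
        p1 = fitted_constrained.predict(table_small.X)[perm]
        p2 = fitted_constrained.predict(table_small.X[perm])
        np.testing.assert_array_equal(p1, p2)

    def test_refit_bitwise_identical(self, table_small):
        cfg = gbm.GBMConfig(seed=11, n_estimators=30, max_depth=3)
        m1 = gbm.fit(table_small.X, table_small.y, cfg,
                     columns=table_small.columns)
        m2 = gbm.fit(table_small.X, table_small.y, cfg,
                     columns=table_small.columns)
        np.testing.assert_array_equal(m1.predict(table_small.X),
                                      m2.predict(table_small.X))

    def test_wrong_column_count(self, fitted_constrained):
        with pytest.raises(ValidationError):
            fitted_constrained.predict(np.ones((3, 2)))


class TestImportance:
    def test_shares_sum_to_one(self, fitted_constrained):
        assert sum(fitted_constrained.importance().values()) \
            == pytest.approx(1.0, abs=1e-9)

    def test_single_feature_gets_all(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 1))
        y = X[:, 0] * 2 + rng.normal(0, 0.1, 200)
        m = gbm.fit(X, y, gbm.GBMConfig(n_estimators=20, seed=0))
        assert m.importance()["x0"] == pytest.approx(1.0)

    def test_top_two_mean_ranks_logp_mw(self, gen_config):
        from toxqsar.partition import kfold
        t = generate(gen_config, 800, seed=61)
        folds = kfold(t.n, 10, seed=2)
        models = []
        cfg = gbm.GBMConfig(constraints=DEFAULT_MONOTONE, seed=7, **FAST)
        for f in range(1, 11):
            tr = folds.train_indices(f)
            models.append(gbm.fit(t.X[tr], t.y[tr], cfg, columns=t.columns))
        avg = gbm.average_importance(models)
        order = sorted(avg, key=lambda c: -avg[c]["mean"])
        assert set(order[:2]) == {"LogP", "MW"}

    def test_unfitted_model_rejected(self):
        m = gbm.GBMModel(gbm.GBMConfig(), ["a"])
        with pytest.raises(ValidationError):
            m.importance()


class TestMonotonicity:
    @pytest.mark.parametrize("feature", ["LogP", "MW", "nDB", "nROH"])
    def test_zero_violations_on_grid(self, fitted_constrained, anchors,
                                     feature):
        assert gbm.check_monotonic(fitted_constrained, anchors, feature,
                                   grid_size=21) == 0

    def test_negative_control_sine(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 4 * np.pi, size=(400, 1))
        y = np.sin(X[:, 0])
        un = gbm.fit(X, y, gbm.GBMConfig(n_estimators=60, seed=0),
                     columns=["x0"])
        con = gbm.GBMModel(un.config, un.columns, un.base_score, un.trees,
                           un.gain, True)
        con.config = gbm.GBMConfig(n_estimators=60, seed=0,
                                   constraints={"x0": 1})
        viol = gbm.check_monotonic(con, X[:50], "x0", grid_size=21)
        assert viol > 0

    def test_grid_size_one_is_zero(self, fitted_constrained, anchors):
        assert gbm.check_monotonic(fitted_constrained, anchors, "LogP",
                                   grid_size=1) == 0

    def test_unconstrained_feature_rejected(self, fitted_constrained,
                                            anchors):
        with pytest.raises(ValidationError, match="sensitivity"):
            gbm.check_monotonic(fitted_constrained, anchors, "GATS1p")

    def test_all_constrained_features_multiple_seeds(self, gen_config):
        t = generate(gen_config, 400, seed=71)
        rng = np.random.default_rng(3)
        anch = t.X[rng.choice(t.n, 50, replace=False)]
        for seed in (1, 2):
            cfg = gbm.GBMConfig(constraints=DEFAULT_MONOTONE, seed=seed,
                                n_estimators=50, max_depth=5)
            m = gbm.fit(t.X, t.y, cfg, columns=t.columns)
            for feature in ("LogP", "MW", "nDB", "nROH"):
                assert gbm.check_monotonic(m, anch, feature, 21) == 0


class TestBoostingDescent:
    def test_training_rmse_nonincreasing_in_estimators(self, table_small):
        # full-sample fits so each round provably reduces training SSE
        cfg = gbm.GBMConfig(subsample=1.0, learning_rate=0.1, seed=0,
                            n_estimators=60, max_depth=3)
        m = gbm.fit(table_small.X, table_small.y, cfg,
                    columns=table_small.columns)
        pred = np.full(table_small.n, m.base_score)
        last = np.inf
        for tree in m.trees:
            pred += cfg.learning_rate * tree.predict(table_small.X)
            rmse = float(np.sqrt(np.mean((table_small.y - pred) ** 2)))
            assert rmse <= last + 1e-9
            last = rmse


class TestSerialization:
    def test_json_roundtrip_predictions(self, fitted_constrained,
                                        table_small):
        back = gbm.GBMModel.from_json(fitted_constrained.to_json())
        np.testing.assert_allclose(back.predict(table_small.X),
                                   fitted_constrained.predict(table_small.X),
                                   rtol=1e-12)
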