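import numpy as np
import pytest
from sklearn.linear_model import ElasticNet as SkEN

from conftest import centered_orthonormal_design
from qpar.elastic_net import (ENPLSRegressor, ElasticNetSelector,
                              fit_elastic_net, fit_en_pls, lambda1_max,
                              tune_en)
from qpar.pls import fit_pls


def soft_threshold(v, t):
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


class TestFitElasticNet:
    def test_unpenalized_equals_least_squares(self, rng):
        X = rng.normal(size=(30, 6))
        y = rng.normal(size=30)
        sel = fit_elastic_net(X, y, lambda1=0.0, lambda2=0.0)
        Xc = X - X.mean(axis=0)
        b_ols = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
        np.testing.assert_allclose(sel.beta, b_ols, atol=1e-6)

    def test_orthonormal_closed_form(self, rng):
        Q = centered_orthonormal_design(25, 8, seed=5)
        y = rng.normal(size=25)
        lam1, lam2 = 0.3, 0.7
        sel = fit_elastic_net(Q, y, lam1, lam2)
        b_ols = Q.T @ (y - y.mean())
        expected = soft_threshold(b_ols, lam1 / 2.0) / (1.0 + lam2)
        np.testing.assert_allclose(sel.beta, expected, atol=1e-8)

    def test_null_condition(self, rng):
        X = rng.normal(size=(20, 10))
        y = rng.normal(size=20)
        lam1 = lambda1_max(X, y)
        sel = fit_elastic_net(X, y, lam1 * (1 + 1e-9), 0.1)
        assert sel.n_selected == 0
        # just below the threshold something survives
        sel2 = fit_elastic_net(X, y, lam1 * 0.99, 0.1)
        assert sel2.n_selected >= 1

    def test_matches_sklearn_parameterization(self, rng):
        """Our (lambda1, lambda2) map onto sklearn's (alpha, l1_ratio) via
        alpha*rho = lambda1/(2n), alpha*(1-rho) = lambda2/n."""
        X = rng.normal(size=(40, 12))
        y = X[:, 1] - 0.5 * X[:, 6] + rng.normal(size=40)
        n = len(y)
        lam1, lam2 = 4.0, 2.0
        a_rho, a_1mrho = lam1 / (2 * n), lam2 / n
        alpha = a_rho + a_1mrho
        ref = SkEN(alpha=alpha, l1_ratio=a_rho / alpha, fit_intercept=True,
                   tol=1e-10, max_iter=100000).fit(X, y)
        sel = fit_elastic_net(X, y, lam1, lam2, tol=1e-10)
        np.testing.assert_allclose(sel.beta, ref.coef_, atol=1e-6)

    def test_kkt_conditions_hold(self, rng):
        X = rng.normal(size=(30, 15))
        y = rng.normal(size=30)
        sel = ElasticNetSelector(lambda1=1.0, lambda2=0.5, tol=1e-8).fit(X, y)
        assert sel.kkt_residual(X, y) < 10 * 1e-8 * max(1.0, np.abs(X.T @ y).max())

    def test_objective_monotone_over_sweeps(self, rng):
        X = rng.normal(size=(20, 8))
        y = rng.normal(size=20)
        Xc, yc = X - X.mean(axis=0), y - y.mean()
        lam1, lam2 = 0.5, 0.2

        def obj(b):
            r = yc - Xc @ b
            return r @ r + lam1 * np.abs(b).sum() + lam2 * b @ b

        objs = []
        for sweeps in range(1, 8):
            sel = ElasticNetSelector(lambda1=lam1, lambda2=lam2, tol=0.0,
                                     max_iter=sweeps).fit(X, y)
            objs.append(obj(sel.coef_))
        assert all(objs[i + 1] <= objs[i] + 1e-10 for i in range(len(objs) - 1))

    def test_grouping_effect_on_duplicated_column(self, rng):
        X = rng.normal(size=(25, 6))
        y = 2.0 * X[:, 0] + rng.normal(size=25, scale=0.1)
        Xd = np.column_stack([X, X[:, 0]])  # duplicate the informative column
        sel = fit_elastic_net(Xd, y, lambda1=0.5, lambda2=1.0, tol=1e-12)
        assert sel.beta[0] == pytest.approx(sel.beta[6], abs=1e-6)
        assert abs(sel.beta[0]) > 0

    def test_negative_penalty_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_elastic_net(rng.normal(size=(10, 3)), rng.normal(size=10), -1.0, 0.0)

    def test_deterministic(self, rng):
        X = rng.normal(size=(20, 10))
        y = rng.normal(size=20)
        a = fit_elastic_net(X, y, 0.5, 0.5)
        b = fit_elastic_net(X, y, 0.5, 0.5)
        np.testing.assert_array_equal(a.beta, b.beta)

    def test_support_consistent_with_beta(self, rng):
        X = rng.normal(size=(20, 10))
        y = rng.normal(size=20)
        sel = fit_elastic_net(X, y, 2.0, 0.1)
        np.testing.assert_array_equal(sel.support, np.flatnonzero(sel.beta))
        assert sel.n_selected == sel.support.size


class TestEnPls:
    def test_lambda1_zero_reduces_to_plain_pls(self, rng):
        X = rng.normal(size=(20, 6))
        y = X @ rng.normal(size=6) + rng.normal(size=20, scale=0.1)
        selection, pls_m = fit_en_pls(X, y, lambda1=0.0, lambda2=0.0, max_components=3)
        assert selection.n_selected == 6
        from qpar.pls import loo_cv
        _, a_opt = loo_cv(X, y, 3)
        plain = fit_pls(X, y, a_opt)
        np.testing.assert_allclose(pls_m.predict(X), plain.predict(X), atol=1e-6)

    def test_support_of_one_gives_one_component(self, rng):
        X = rng.normal(size=(20, 5))
        y = 3.0 * X[:, 2] + rng.normal(size=20, scale=0.05)
        l1m = lambda1_max(X, y)
        selection, pls_m = fit_en_pls(X, y, lambda1=0.9 * l1m, lambda2=0.0)
        if selection.n_selected == 1:
            assert pls_m.n_components_ == 1

    def test_empty_support_raises_helpful_error(self, rng):
        X = rng.normal(size=(15, 5))
        y = rng.normal(size=15)
        with pytest.raises(ValueError, match="lambda1"):
            ENPLSRegressor(lambda1=10 * lambda1_max(X, y), lambda2=0.1).fit(X, y)

    def test_estimator_clonable(self):
        from sklearn.base import clone
        est = ENPLSRegressor(lambda1=1.0, lambda2=2.0, max_components=5)
        c = clone(est)
        assert c.get_params() == est.get_params()


class TestTuneEn:
    def test_single_point_grid_returned(self, rng):
        X = rng.normal(size=(20, 6))
        y = X[:, 0] + rng.normal(size=20, scale=0.1)
        l1, l2, results = tune_en(X, y, [0.5], [0.1], folds=4)
        assert (l1, l2) == (0.5, 0.1)
        assert set(results) == {(0.5, 0.1)}

    def test_grid_size_accounting_loo(self, rng):
        X = rng.normal(size=(9, 4))
        y = X[:, 0] + rng.normal(size=9, scale=0.1)
        _, _, results = tune_en(X, y, [0.2, 0.6], [0.1], folds=9)
        assert len(results) == 2  # one CV score per grid point

    def test_sparsity_induced_on_sparse_truth(self):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            X = r.normal(size=(30, 60))
            beta = np.zeros(60)
            beta[:5] = r.uniform(1, 2, size=5)
            y = X @ beta + r.normal(size=30, scale=0.5)
            l1m = lambda1_max(X, y)
            l1, _, _ = tune_en(X, y, list(l1m * np.geomspace(0.5, 1e-3, 6)),
                               [0.1], folds=3, max_components=5)
            if l1 > 0:
                hits += 1
        assert hits >= 0.8 * n_seeds

    def test_negative_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            tune_en(rng.normal(size=(10, 3)), rng.normal(size=10), [-0.1], [0.1], folds=2)

    def test_bad_folds_rejected(self, rng):
        with pytest.raises(ValueError):
            tune_en(rng.normal(size=(10, 3)), rng.normal(size=10), [0.1], [0.1], folds=1)
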