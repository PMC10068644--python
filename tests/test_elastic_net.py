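"""Literal sum-of-squares elastic net, grid search and bootstrap averaging."""

import numpy as np
import pandas as pd
import pytest

from glucometab.elastic_net import (ElasticNetConfig, ElasticNetError,
                                    ElasticNetProblem, bootstrap_model_average,
                                    fit_scaled_elastic_net, lambda_max,
                                    objective_value, predict_model_average,
                                    select_l2_by_grid)

from conftest import make_null_problem


def make_problem(n=300, p=40, seed=7, beta=None, noise=1.0):
    X, y = make_null_problem(n, p, seed, beta, noise)
    return ElasticNetProblem(y, X, [f"M{j:02d}" for j in range(p)])


class TestCoordinateDescent:
    def test_lambda_zero_equals_ols(self):
        prob = make_problem(beta=np.r_[[0.5, -0.4, 0.3, 0.2], np.zeros(36)])
        fit = fit_scaled_elastic_net(prob, 0.5, 0.0)
        Xi = np.column_stack([np.ones(len(prob.y)), prob.X])
        ols = np.linalg.lstsq(Xi, prob.y, rcond=None)[0]
        assert np.max(np.abs(fit.beta - ols[1:])) < 1e-6
        assert fit.intercept == pytest.approx(ols[0], abs=1e-6)

    def test_ridge_single_predictor_closed_form(self):
        # stationarity of the literal objective: beta = 2 Sxy / (2 Sxx + lam)
        prob = make_problem(p=1, beta=[0.4])
        lam = 123.0
        fit = fit_scaled_elastic_net(prob, 0.0, lam)
        x, yc = prob.X[:, 0], prob.y - prob.y.mean()
        closed = 2 * (x @ yc) / (2 * (x @ x) + lam)
        assert fit.beta[0] == pytest.approx(closed, abs=1e-8)

    def test_full_shrinkage_above_lambda_max(self):
        prob = make_problem(beta=np.r_[[0.5], np.zeros(39)])
        lam = lambda_max(prob.X, prob.y, 1.0) * 1.001
        fit = fit_scaled_elastic_net(prob, 1.0, lam)
        assert np.all(fit.beta == 0.0)
        assert fit.intercept == pytest.approx(prob.y.mean())
        just_below = fit_scaled_elastic_net(prob, 1.0, lam * 0.99)
        assert len(just_below.active) >= 1

    def test_matches_sklearn_penalty_mapping(self):
        """Cross-check against scikit-learn via a = lambda/(2n), l1_ratio = alpha."""
        from sklearn.linear_model import ElasticNet

        prob = make_problem(beta=np.r_[[0.5, -0.4, 0.3], np.zeros(37)])
        n = len(prob.y)
        for alpha, lam in [(0.5, 30.0), (1.0, 60.0), (0.2, 10.0)]:
            fit = fit_scaled_elastic_net(prob, alpha, lam)
            sk = ElasticNet(alpha=lam / (2 * n), l1_ratio=alpha,
                            fit_intercept=True, tol=1e-12, max_iter=200000)
            sk.fit(prob.X, prob.y)
            assert np.max(np.abs(fit.beta - sk.coef_)) < 1e-8

    def test_objective_never_below_converged_value_on_perturbation(self):
        prob = make_problem(beta=np.r_[[0.5, -0.4], np.zeros(38)])
        fit = fit_scaled_elastic_net(prob, 0.5, 25.0)
        rng = np.random.default_rng(0)
        for _ in range(20):
            pert = fit.beta + rng.normal(0, 1e-4, len(fit.beta))
            assert objective_value(prob.y, prob.X, fit.intercept, pert,
                                   0.5, 25.0) >= fit.objective - 1e-9

    def test_l1_norm_non_increasing_along_lambda_path(self):
        prob = make_problem(beta=np.r_[[0.5, -0.4, 0.3], np.zeros(37)])
        lmax = lambda_max(prob.X, prob.y, 0.5)
        norms = []
        for lam in np.geomspace(1e-3 * lmax, lmax, 10):
            fit = fit_scaled_elastic_net(prob, 0.5, lam)
            norms.append(np.abs(fit.beta).sum())
        assert all(b <= a + 1e-9 for a, b in zip(norms, norms[1:]))

    def test_zero_variance_column_rejected_at_construction(self):
        X, y = make_null_problem(100, 5, seed=1)
        X[:, 2] = 0.0
        with pytest.raises(ElasticNetError, match="zero-variance"):
            ElasticNetProblem(y, X, [f"M{j}" for j in range(5)])

    def test_unstandardized_input_rejected(self):
        X, y = make_null_problem(100, 5, seed=2)
        with pytest.raises(ElasticNetError, match="standardized"):
            ElasticNetProblem(y, X * 3.0, [f"M{j}" for j in range(5)])


class TestGridSearch:
    def test_single_point_grid_returned(self):
        prob = make_problem()
        lam, diag = select_l2_by_grid(prob, 0.5, grid=np.array([17.0]))
        assert lam == 17.0
        assert len(diag) == 1

    def test_chosen_lambda_attains_grid_maximum(self):
        prob = make_problem(beta=np.r_[[0.5, -0.4], np.zeros(38)])
        lam, diag = select_l2_by_grid(prob, 0.5, n_grid=12)
        ok = diag[np.isfinite(diag["adj_r2"])]
        assert lam == ok.loc[ok["adj_r2"].idxmax(), "lambda"] or (
            diag.loc[np.isclose(diag["adj_r2"], ok["adj_r2"].max()),
                     "lambda"].max() == lam)
        # brute-force re-check: refit at every grid point
        for _, row in ok.iterrows():
            refit = fit_scaled_elastic_net(prob, 0.5, row["lambda"])
            assert refit.adj_r2 == pytest.approx(row["adj_r2"], abs=1e-8)

    def test_pure_noise_prefers_upper_half_of_grid(self):
        prob = make_problem(n=200, p=50, seed=13)   # no signal
        lam, diag = select_l2_by_grid(prob, 0.5)
        grid = np.sort(diag["lambda"].to_numpy())
        assert lam >= grid[len(grid) // 2]

    def test_empty_grid_rejected(self):
        with pytest.raises(ElasticNetError):
            select_l2_by_grid(make_problem(), 0.5, grid=np.array([]))


class TestBootstrap:
    def test_forced_selection_with_identical_draws(self):
        # one overwhelming predictor, lasso penalty between its threshold and
        # the others', and train_fraction ~ 1 so every draw is the full sample
        rng = np.random.default_rng(21)
        n = 120
        X = rng.normal(size=(n, 3))
        X = (X - X.mean(0)) / X.std(0)
        y = 2.0 * X[:, 1] + 0.01 * rng.normal(size=n)
        prob = ElasticNetProblem(y, X, ["Ma", "Mb", "Mc"])
        grads = 2 * np.abs(X.T @ (y - y.mean()))
        lam = 0.5 * (grads[1] + np.sort(grads)[-2])   # only Mb survives
        cfg = ElasticNetConfig(alpha=1.0, lambda_=lam, n_bootstrap=2,
                               train_fraction=0.999, cluster_bootstrap=False,
                               seed=0)
        res = bootstrap_model_average(prob, cfg)
        assert res.table.loc["Mb", "nonzero_pct"] == 100.0
        assert res.table.loc[["Ma", "Mc"], "nonzero_pct"].eq(0.0).all()
        # refit OLS on the single active column
        Xa = np.column_stack([np.ones(n), X[:, 1]])
        coef = np.linalg.lstsq(Xa, y, rcond=None)[0]
        assert res.table.loc["Mb", "beta_star"] == pytest.approx(coef[1], rel=1e-9)
        assert res.selected == ["Mb"]

    def test_threshold_is_strictly_greater_than(self):
        table = pd.DataFrame({"nonzero_pct": [20.1, 20.0, 19.9]},
                             index=["a", "b", "c"])
        sel = table["nonzero_pct"] > 100 * 0.20
        assert sel.tolist() == [True, False, False]

    def test_planted_truth_recovery(self):
        beta = np.zeros(50)
        truth = [3, 11, 22, 33, 44]
        beta[truth] = 0.3
        prob = make_problem(n=500, p=50, seed=11, beta=beta)
        cfg = ElasticNetConfig(alpha=0.5, n_bootstrap=100, seed=9,
                               cluster_bootstrap=False)
        res = bootstrap_model_average(prob, cfg)
        true_ids = [prob.metabolite_ids[j] for j in truth]
        assert res.table.loc[true_ids, "selected"].all()
        null_pct = res.table.drop(index=true_ids)["nonzero_pct"]
        assert res.table.loc[true_ids, "nonzero_pct"].mean() > null_pct.mean()

    def test_reproducible_given_seed(self):
        prob = make_problem(n=150, p=10, seed=3,
                            beta=np.r_[[0.5], np.zeros(9)])
        cfg = ElasticNetConfig(alpha=0.5, n_bootstrap=25, seed=4,
                               cluster_bootstrap=False)
        a = bootstrap_model_average(prob, cfg)
        b = bootstrap_model_average(prob, cfg)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_cluster_bootstrap_draws_whole_families(self):
        rng = np.random.default_rng(5)
        n, p = 200, 4
        X = rng.normal(size=(n, p))
        X = (X - X.mean(0)) / X.std(0)
        y = X[:, 0] * 0.5 + rng.normal(size=n)
        fam = np.repeat(np.arange(20), 10)
        prob = ElasticNetProblem(y, X, list("abcd"), family=fam)
        cfg = ElasticNetConfig(alpha=0.5, lambda_=5.0, n_bootstrap=10, seed=6)
        res = bootstrap_model_average(prob, cfg)   # exercises the family path
        assert res.n_bootstrap == 10

    def test_config_validation(self):
        with pytest.raises(ElasticNetError):
            ElasticNetConfig(alpha=1.5)
        with pytest.raises(ElasticNetError):
            ElasticNetConfig(train_fraction=1.0)


class TestPrediction:
    def test_all_zero_coefficients_predict_intercept(self):
        prob = make_problem(n=100, p=5, seed=8)
        lam = lambda_max(prob.X, prob.y, 1.0) * 1.1
        cfg = ElasticNetConfig(alpha=1.0, lambda_=lam, n_bootstrap=5,
                               cluster_bootstrap=False, seed=0, refit=True)
        res = bootstrap_model_average(prob, cfg)
        pred = predict_model_average(res, prob.X)
        assert np.allclose(pred, res.intercept_star)

    def test_averaging_predictions_equals_predicting_with_average(self):
        # Eq-style linearity: mean_i X b^(i) == X mean_i b^(i)
        rng = np.random.default_rng(12)
        X = rng.normal(size=(50, 6))
        betas = rng.normal(size=(30, 6))
        avg_pred = np.mean([X @ b for b in betas], axis=0)
        assert np.max(np.abs(avg_pred - X @ betas.mean(0))) < 1e-10

    def test_dimension_mismatch_rejected(self):
        prob = make_problem(n=80, p=4, seed=9)
        cfg = ElasticNetConfig(alpha=0.5, lambda_=10.0, n_bootstrap=3,
                               cluster_bootstrap=False, seed=1)
        res = bootstrap_model_average(prob, cfg)
        with pytest.raises(ElasticNetError):
            predict_model_average(res, np.ones((5, 7)))
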