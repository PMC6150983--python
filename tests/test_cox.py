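"""Breslow Cox machinery: fits, baseline, residuals, null covariance, CV."""

import numpy as np
import pytest
from scipy.optimize import minimize

import ogsurv as og
from ogsurv import cox
from ogsurv.cox import (baseline_hazard, cox_log_partial_likelihood, cox_path,
                        cv_select_lambda, fit_cox, lambda_max,
                        martingale_residuals, null_covariance)

from conftest import simulate_simple_cox


def breslow_neg_lpl_reference(beta, X, time, status):
    """Independent textbook implementation: event terms minus log risk sums."""
    eta = X @ np.atleast_1d(beta)
    out = 0.0
    for i in range(len(time)):
        if status[i] == 1:
            risk = eta[time >= time[i]]
            m = risk.max()
            out -= eta[i] - (m + np.log(np.exp(risk - m).sum()))
    return out


class TestUnpenalizedFit:
    def test_matches_lifelines(self, small_cox_data):
        from lifelines import CoxPHFitter
        import pandas as pd

        X, time, status = small_cox_data
        fit = fit_cox(X, (time, status), penalty="none")
        df = pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
        df["T"], df["E"] = time, status
        ll = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(fit.coef_, ll.params_.values, atol=1e-6)

    def test_five_subject_fixture_against_newton_on_written_likelihood(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        status = np.array([1, 1, 0, 1, 0])
        X = np.array([[1.0], [0.0], [1.0], [0.0], [1.0]])
        fit = fit_cox(X, (time, status), penalty="none", tol=1e-12)
        res = minimize(breslow_neg_lpl_reference, x0=[0.0],
                       args=(X, time, status), method="BFGS", tol=1e-12)
        assert abs(fit.coef_[0] - res.x[0]) < 1e-6

    def test_parameter_recovery(self):
        rng = np.random.default_rng(11)
        X, time, status = simulate_simple_cox(rng, 5000, [1.0])
        fit = fit_cox(X, (time, status), penalty="none")
        assert abs(fit.coef_[0] - 1.0) < 0.1

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            fit_cox(np.ones((3, 1)), ([1.0, 2.0, 3.0], [0, 0, 0]))


class TestPenalizedFit:
    def test_lasso_at_lambda_max_is_all_zero(self, small_cox_data):
        X, time, status = small_cox_data
        lmax = lambda_max(X, (time, status))
        fit = fit_cox(X, (time, status), penalty="lasso", lam=lmax * (1 + 1e-8))
        assert np.all(fit.coef_ == 0.0)
        fit2 = fit_cox(X, (time, status), penalty="lasso", lam=lmax * 0.8)
        assert np.any(fit2.coef_ != 0.0)

    def test_singleton_group_lasso_equals_lasso(self, small_cox_data):
        X, time, status = small_cox_data
        lam = 0.5 * lambda_max(X, (time, status))
        la = fit_cox(X, (time, status), penalty="lasso", lam=lam)
        gl = fit_cox(X, (time, status), penalty="group_lasso", lam=lam,
                     groups=np.arange(X.shape[1]), group_weights=np.ones(X.shape[1]))
        np.testing.assert_allclose(la.coef_, gl.coef_, atol=1e-6)

    def test_lasso_matches_coxnet(self, small_cox_data):
        from sksurv.linear_model import CoxnetSurvivalAnalysis
        from ogsurv.util import as_structured_y

        X, time, status = small_cox_data
        lam = 0.3 * lambda_max(X, (time, status))
        mine = fit_cox(X, (time, status), penalty="lasso", lam=lam)
        cn = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[lam], normalize=False,
                                    fit_baseline_model=False, tol=1e-9)
        cn.fit(X, as_structured_y(time, status))
        np.testing.assert_allclose(mine.coef_, cn.coef_.ravel(), atol=2e-4)

    def test_lasso_path_support_shrinks_with_penalty(self, small_cox_data):
        X, time, status = small_cox_data
        lmax = lambda_max(X, (time, status))
        grid = np.geomspace(lmax, 0.01 * lmax, 12)
        coefs = cox_path(X, (time, status), "lasso", grid)
        nnz = (coefs != 0).sum(axis=1)
        assert (np.diff(nnz) >= 0).all()  # grid descends, support grows

    def test_newton_objective_decreases_monotonically(self, small_cox_data):
        X, time, status = small_cox_data
        for pen, lam in (("none", 0.0), ("ridge", 0.3)):
            fit = fit_cox(X, (time, status), penalty=pen, lam=lam)
            path = np.asarray(fit.objective_path)
            assert (np.diff(path) <= 1e-12).all()

    def test_wide_ridge_reduction_matches_direct_newton(self):
        rng = np.random.default_rng(3)
        X, time, status = simulate_simple_cox(rng, 50, [1.0] + [0.0] * 79)
        lam = 0.7
        reduced = fit_cox(X, (time, status), penalty="ridge", lam=lam)
        prep = cox._CoxPrep(time, status)
        direct, _, _, _ = cox._newton(prep, X[prep.order], lam, None, 1e-10, 200)
        np.testing.assert_allclose(reduced.coef_, direct, atol=1e-6)

    def test_groups_penalty_consistency_checked(self, small_cox_data):
        X, time, status = small_cox_data
        with pytest.raises(ValueError, match="groups"):
            fit_cox(X, (time, status), penalty="lasso", groups=np.zeros(X.shape[1]))


class TestBaselineAndResiduals:
    def test_two_subject_hand_example(self):
        time, status = [1.0, 2.0], [1, 1]
        bh = baseline_hazard(time, status)
        np.testing.assert_allclose(bh.increments, [0.5, 1.0])
        np.testing.assert_allclose(bh.cumulative_at([1.0, 2.0]), [0.5, 1.5])
        np.testing.assert_allclose(martingale_residuals(time, status), [0.5, -0.5])
        np.testing.assert_allclose(null_covariance(time, status),
                                   [[0.25, -0.25], [-0.25, 0.25]])

    def test_single_event_subject(self):
        bh = baseline_hazard([3.0], [1])
        np.testing.assert_allclose(bh.cumulative_at(3.0), [1.0])

    def test_censored_before_first_event_has_zero_residual(self):
        m = martingale_residuals([0.5, 1.0, 2.0], [0, 1, 1])
        assert m[0] == 0.0

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError):
            baseline_hazard([1.0, 2.0], [0, 0])

    def test_null_baseline_equals_nelson_aalen(self, small_cox_data):
        from lifelines import NelsonAalenFitter

        _, time, status = small_cox_data
        bh = baseline_hazard(time, status)
        naf = NelsonAalenFitter(nelson_aalen_smoothing=False).fit(time, status)
        grid = np.sort(time)
        np.testing.assert_allclose(
            bh.cumulative_at(grid),
            naf.cumulative_hazard_.loc[grid].values.ravel(), atol=1e-10)

    def test_residuals_sum_to_zero(self, small_cox_data):
        _, time, status = small_cox_data
        assert abs(martingale_residuals(time, status).sum()) < 1e-10

    def test_null_covariance_structure(self, small_cox_data):
        _, time, status = small_cox_data
        V = null_covariance(time, status)
        np.testing.assert_allclose(V, V.T, atol=1e-12)
        assert np.abs(V.sum(axis=1)).max() < 1e-10       # rows sum to zero
        assert np.linalg.eigvalsh(V).min() > -1e-10      # positive semidefinite


class TestCrossValidation:
    def test_selected_lambda_in_grid_and_deterministic(self, small_cox_data):
        X, time, status = small_cox_data
        sel1 = cv_select_lambda(X, (time, status), "lasso", seed=4, grid_size=20)
        sel2 = cv_select_lambda(X, (time, status), "lasso", seed=4, grid_size=20)
        assert sel1.lam in sel1.grid
        assert sel1.lam == sel2.lam
        np.testing.assert_array_equal(sel1.cv_deviance, sel2.cv_deviance)

    def test_pure_noise_selects_sparse_model(self):
        rng = np.random.default_rng(21)
        X, time, status = simulate_simple_cox(rng, 200, [0.0] * 20)
        sel = cv_select_lambda(X, (time, status), "lasso", seed=0, grid_size=30)
        fit = fit_cox(X, (time, status), penalty="lasso", lam=sel.lam)
        assert (fit.coef_ != 0).sum() <= 6

    def test_too_few_events_for_stratification(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        status = np.array([1, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="fold|strat"):
            cv_select_lambda(np.ones((6, 1)), (time, status), "lasso",
                             n_folds=5, seed=0)


def test_log_partial_likelihood_stable_at_extreme_predictors():
    """Linear predictors spanning hundreds of log-units stay finite and exact."""
    rng = np.random.default_rng(2)
    n = 80
    eta = rng.normal(0.0, 60.0, n)
    T = rng.exponential(1.0 / (0.1 * np.exp(np.clip(eta, -300, 300))))
    status = np.ones(n, dtype=int)
    lpl = cox_log_partial_likelihood(eta, T, status)
    from scipy.special import logsumexp

    ref = 0.0
    order = np.argsort(T)
    eta_s, t_s = eta[order], T[order]
    for i in range(n):
        ref += eta_s[i] - logsumexp(eta_s[t_s >= t_s[i]])
    assert np.isfinite(lpl)
    np.testing.assert_allclose(lpl, ref, rtol=1e-10)
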