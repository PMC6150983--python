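"""The OGS pipeline and comparator estimators on small scenarios."""

import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

import ogsurv as og
from ogsurv.estimators import (OracleCox, OrdinaryLassoCox, OverlapGroupLassoCox,
                               OverlappingGroupScreeningCox,
                               UnivariateSelectionCox, _univariate_cox_stats,
                               permutation_cutoff, step3_select_interactions)
from ogsurv.skat import standardized_products

from conftest import simulate_simple_cox


def toy_pathway_data(seed, n=300, causal_effect=1.2, with_pair=False):
    """Two disjoint 6-gene pathways; pathway 1 causal, pathway 2 inert."""
    coll = og.build_chain_structure([6, 6], [0])
    rng = np.random.default_rng(seed)
    beta = np.zeros(12)
    beta[:6] = causal_effect
    X = og.make_covariates(n, 12, 0.5, rng)
    eta = X @ beta
    if with_pair:
        eta = eta + 2.0 * X[:, 6] * X[:, 7]
    T = rng.exponential(1.0 / (0.1 * np.exp(np.clip(eta, -300, 300))))
    C = np.quantile(T, 0.75) * rng.uniform(0, 2, n)
    Xdf = pd.DataFrame(X, columns=list(coll.gene_universe))
    return coll, Xdf, (np.minimum(T, C), (T <= C).astype(int))


class TestOgsPipeline:
    def test_step1_selects_the_causal_pathway(self):
        hits, extras = 0, 0
        for s in range(10):
            coll, X, y = toy_pathway_data(700 + s)
            est = OverlapGroupLassoCox(pathways=coll, random_state=s,
                                       n_lambda=40)
            est.fit(X, y)
            hits += int(0 in est.m_main_)
            extras += int(1 in est.m_main_)
        assert hits >= 9          # causal pathway nearly always found

    def test_deterministic_under_fixed_seed(self):
        coll, X, y = toy_pathway_data(3, with_pair=True)
        fits = []
        for _ in range(2):
            est = OverlappingGroupScreeningCox(pathways=coll, penalty="lasso",
                                               random_state=7)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(X, y)
            fits.append(est)
        a, b = fits
        assert a.screening_.m_main == b.screening_.m_main
        assert a.screening_.c_int == b.screening_.c_int
        assert a.screening_.m_int == b.screening_.m_int
        np.testing.assert_array_equal(a.coef_, b.coef_)

    def test_ridge_final_model_retains_every_candidate(self):
        coll, X, y = toy_pathway_data(5, with_pair=True)
        est = OverlappingGroupScreeningCox(pathways=coll, penalty="ridge",
                                           random_state=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X, y)
        if est.screening_.m_main:
            assert (est.coef_ != 0.0).all()
            n_cand = (len(est.screening_.candidate_genes)
                      + len(est.screening_.candidate_pairs))
            assert len(est.coef_) == n_cand

    def test_lasso_support_is_subset_of_candidates(self):
        coll, X, y = toy_pathway_data(6, with_pair=True)
        est = OverlappingGroupScreeningCox(pathways=coll, penalty="lasso",
                                           random_state=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X, y)
        cand = set(est.model_feature_names_)
        assert set(est.selected_features_) <= cand
        scr = est.screening_
        assert set(scr.m_int) <= {g.gid for g in scr.groups}
        for g in scr.groups:
            assert all(i < j for i, j in g.pairs)

    def test_null_data_gives_coin_flip_concordance(self):
        cs = []
        for s in range(12):
            coll, X, y = toy_pathway_data(900 + s, causal_effect=0.0)
            Xte_coll, Xte, yte = toy_pathway_data(950 + s, causal_effect=0.0)
            est = OverlappingGroupScreeningCox(pathways=coll, penalty="lasso",
                                               random_state=s)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(X, y)
            cs.append(og.c_index(est.predict(Xte), yte))
        assert abs(np.median(cs) - 0.5) <= 0.05

    def test_sklearn_params_round_trip(self):
        coll = og.build_chain_structure([3, 3], [1])
        est = OverlappingGroupScreeningCox(pathways=coll, penalty="ridge",
                                           n_perm=2, random_state=9)
        params = est.get_params()
        assert params["penalty"] == "ridge" and params["n_perm"] == 2
        est2 = clone(est).set_params(penalty="lasso")
        assert est2.penalty == "lasso" and est2.random_state == 9


class TestStep3Rules:
    def test_strict_inequality_at_the_cutoff(self):
        assert step3_select_interactions([0.2, 0.05, 0.0499], 0.05) == [2]
        assert step3_select_interactions([0.5, 0.9], 0.1) == []

    def test_cutoff_is_minimum_of_null_pvalues(self, small_cox_data):
        X, time, status = small_cox_data
        R1, _ = standardized_products(X, [(0, 1), (2, 3)])
        R2, _ = standardized_products(X, [(1, 4)])
        c_int, p_null = permutation_cutoff(X, (time, status), [R1, R2],
                                           n_perm=2, seed=0, weight_ridge=1.0)
        assert c_int == p_null.min()
        assert len(p_null) == 4
        c1, p1 = permutation_cutoff(X, (time, status), [R1], n_perm=1, seed=1,
                                    weight_ridge=1.0)
        assert c1 == p1[0] and len(p1) == 1


class TestComparators:
    def test_oracle_has_perfect_selection_metrics(self):
        coll, X, y = toy_pathway_data(8, with_pair=True)
        truth = og.TrueModel(
            beta_main=np.concatenate([np.full(6, 1.2), np.zeros(6)]),
            interaction_pairs=[(6, 7)], beta_int=np.array([2.0]),
            effective_pathways=[0], gene_names=list(X.columns))
        est = OracleCox(true_model=truth).fit(X, y)
        rep = og.evaluate_model(est, truth, og.SurvivalDataset(X=X, time=y[0],
                                                               status=y[1]))
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0
        assert rep.t_model == 1 and rep.tint_model == 1
        signs = np.sign(est.coef_)
        truth_signs = np.sign(np.concatenate([np.full(6, 1.2), [2.0]]))
        np.testing.assert_array_equal(signs, truth_signs)

    def test_univariate_stats_match_per_feature_fits(self, small_cox_data):
        X, time, status = small_cox_data
        b, p = _univariate_cox_stats(X, time, status)
        for j in range(X.shape[1]):
            single = og.fit_cox(X[:, [j]], (time, status), penalty="none")
            assert abs(b[j] - single.coef_[0]) < 1e-6

    def test_univariate_selection_finds_strong_feature_controls_noise(self):
        rng = np.random.default_rng(31)
        X, time, status = simulate_simple_cox(rng, 300, [1.5] + [0.0] * 11)
        Xdf = pd.DataFrame(X, columns=[f"g{i + 1}" for i in range(12)])
        est = UnivariateSelectionCox().fit(Xdf, (time, status))
        assert "g1" in est.selected_features_
        # pure noise: no survivors for most seeds
        zeros = 0
        for s in range(3):
            rng = np.random.default_rng(40 + s)
            X, time, status = simulate_simple_cox(rng, 250, [0.0] * 10)
            est = UnivariateSelectionCox().fit(
                pd.DataFrame(X, columns=[f"g{i + 1}" for i in range(10)]),
                (time, status))
            zeros += int(len(est.selected_features_) == 0)
        assert zeros >= 2

    def test_ordinary_lasso_universe_and_pruning(self):
        coll, X, y = toy_pathway_data(12, with_pair=True)
        est = OrdinaryLassoCox(random_state=0).fit(X, y)
        assert len(est.model_feature_names_) == og.interaction_universe_size(12)
        assert 0 < len(est.selected_features_) < 78

    def test_overlap_lasso_has_no_interaction_columns(self):
        coll, X, y = toy_pathway_data(13)
        est = OverlapGroupLassoCox(pathways=coll, random_state=0).fit(X, y)
        assert all(":" not in name for name in est.model_feature_names_)
        assert len(est.coef_) == 12

    def test_overlap_lasso_disjoint_equals_plain_group_lasso(self):
        coll, X, y = toy_pathway_data(14)
        est = OverlapGroupLassoCox(pathways=coll, random_state=1).fit(X, y)
        # disjoint pathways: latent design is a column permutation of the
        # gene design, so the collapsed fit solves the plain group lasso
        Xs = (X.values - X.values.mean(0)) / X.values.std(0)
        groups = np.repeat([0, 1], 6)
        direct = og.fit_cox(Xs, y, penalty="group_lasso", lam=est.lambda_,
                            groups=groups)
        np.testing.assert_allclose(np.sort(est.coef_), np.sort(direct.coef_),
                                   atol=1e-5)


class TestPrediction:
    def test_predict_uses_training_statistics(self):
        coll, X, y = toy_pathway_data(20, with_pair=True)
        est = OverlappingGroupScreeningCox(pathways=coll, penalty="lasso",
                                           random_state=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X, y)
        _, Xte, _ = toy_pathway_data(21, with_pair=True)
        pi = est.predict(Xte)
        assert pi.shape == (len(Xte),)
        F = est._model_features(est._transform(Xte))
        np.testing.assert_allclose(pi, F @ est.coef_)
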