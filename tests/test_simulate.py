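"""Synthetic-data generator: covariate law, true models, censoring, I/O."""

import numpy as np
import pytest

import ogsurv as og
from ogsurv.simulate import (CHAIN_SPECS, EFFECT_SPECS, SimulationScenario,
                             build_interaction_features, calibrate_censoring_tau,
                             interaction_universe_size, make_covariates,
                             make_dataset, make_true_model, read_dataset,
                             setting_collection, simulate_survival,
                             write_dataset)
from ogsurv.pathways import expand


class TestCovariates:
    def test_ar1_correlation_law(self):
        X = make_covariates(100_000, 3, 0.5, seed=0)
        corr = np.corrcoef(X.T)
        assert abs(corr[0, 1] - 0.5) < 0.01
        assert abs(corr[0, 2] - 0.25) < 0.01
        assert np.abs(X.std(axis=0) - 1.0).max() < 0.02

    def test_single_gene_unit_variance(self):
        X = make_covariates(50_000, 1, 0.5, seed=1)
        assert abs(X.var() - 1.0) < 0.02

    def test_deterministic_under_fixed_seed(self):
        a = make_covariates(100, 10, 0.5, seed=42)
        b = make_covariates(100, 10, 0.5, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            make_covariates(10, 3, 1.0)


class TestTrueModel:
    @pytest.mark.parametrize("setting,pattern,count", [
        (1, "within", 45), (1, "between", 45), (1, "coexist", 48),
        (2, "within", 84), (2, "between", 84), (2, "coexist", 87)])
    def test_effective_term_counts(self, setting, pattern, count):
        coll = setting_collection(setting)
        sc = SimulationScenario(setting=setting, pattern=pattern)
        truth = make_true_model(sc, coll, expand(coll))
        assert truth.n_effective == count

    def test_shared_genes_keep_constant_pathway_effect(self):
        # genes shared between an effective and an ineffective pathway carry
        # only the effective pathway's latent constant
        coll = setting_collection(1)
        sc = SimulationScenario(setting=1, pattern="within")
        truth = make_true_model(sc, coll, expand(coll))
        gidx = coll.gene_index()
        p2 = [gidx[g] for g in coll.members[1]]
        assert set(np.round(truth.beta_main[p2], 12)) == {4.5}
        p4 = [gidx[g] for g in coll.members[3]]
        assert set(np.round(truth.beta_main[p4], 12)) == {-3.0}

    def test_interaction_pairs_lie_in_stated_pathways(self):
        coll = setting_collection(2)
        spec = EFFECT_SPECS[2]
        members7 = set(coll.members[6])
        for i, j in spec["within_pairs"]:
            assert f"g{i}" in members7 and f"g{j}" in members7
        members13, members14 = set(coll.members[12]), set(coll.members[13])
        for i, j in spec["between_pairs"]:
            assert f"g{i}" in members13 and f"g{j}" in members14

    def test_mismatched_collection_rejected(self):
        sc = SimulationScenario(setting=2)
        coll = setting_collection(1)
        with pytest.raises(ValueError):
            make_true_model(sc, coll, expand(coll))


class TestSurvivalGeneration:
    def test_exponential_mean_without_effects(self):
        coll = og.build_chain_structure([2, 2], [0])
        truth = og.TrueModel(beta_main=np.zeros(4), interaction_pairs=[],
                             beta_int=np.empty(0), effective_pathways=[],
                             gene_names=list(coll.gene_universe))
        X = np.zeros((100_000, 4))
        ds = simulate_survival(X, truth, baseline_rate=0.1, seed=3, tau=1e9)
        assert abs(ds.time.mean() - 10.0) < 0.2     # Exp(0.1) mean, no censoring
        assert ds.status.mean() > 0.999

    def test_censoring_calibration_hits_target(self, setting1_tau):
        rates = []
        for s in range(10):
            sc = SimulationScenario(setting=1, pattern="within", seed=600 + s)
            train, _, _, _ = make_dataset(sc, tau=setting1_tau)
            rates.append(train.censoring_rate)
        assert abs(np.mean(rates) - 0.50) < 0.02

    def test_censored_times_bounded_by_tau(self, setting1_tau):
        sc = SimulationScenario(setting=1, pattern="within", seed=601)
        train, _, _, _ = make_dataset(sc, tau=setting1_tau)
        assert train.time[train.status == 0].max() <= setting1_tau
        assert (train.time > 0).all()
        assert set(np.unique(train.status)) <= {0, 1}

    def test_calibration_tolerance_for_65_percent(self):
        coll = setting_collection(1)
        sc = SimulationScenario(setting=1, pattern="within", censoring_target=0.65)
        truth = make_true_model(sc, coll, expand(coll))
        tau = calibrate_censoring_tau(truth, 0.65, seed=9, n_pilot=50_000)
        # expected censoring at tau on an independent pilot
        rng = np.random.default_rng(10)
        X = make_covariates(50_000, coll.q, 0.5, rng)
        eta = np.clip(truth.linear_predictor(X), -300, 300)
        T = rng.exponential(1.0 / (0.1 * np.exp(eta)))
        with np.errstate(over="ignore"):
            achieved = np.minimum(T / tau, 1.0).mean()
        assert abs(achieved - 0.65) < 0.015

    def test_parameter_recovery_reduced_effects(self):
        """Unpenalized Cox on the true support recovers a scaled-down model."""
        coll = setting_collection(1)
        sc = SimulationScenario(setting=1, pattern="coexist", seed=5)
        truth = make_true_model(sc, coll, expand(coll))
        truth.beta_main = truth.beta_main * 0.2
        truth.beta_int = truth.beta_int * 0.2
        rng = np.random.default_rng(17)
        X = make_covariates(5000, coll.q, 0.5, rng)
        ds = simulate_survival(X, truth, seed=18, tau=1e12)
        support = np.flatnonzero(truth.beta_main)
        F = np.column_stack([X[:, support]]
                            + [X[:, i] * X[:, j] for i, j in truth.interaction_pairs])
        beta_true = np.concatenate([truth.beta_main[support], truth.beta_int])
        fit = og.fit_cox(F, ds.y, penalty="none")
        rel = np.abs(fit.coef_ - beta_true) / np.abs(beta_true)
        assert rel.max() < 0.10


class TestInteractionFeatures:
    def test_universe_sizes(self):
        assert interaction_universe_size(81) == 3321
        assert interaction_universe_size(462) == 106_953

    def test_columns_standardized_and_named(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((200, 5))
        X = (X - X.mean(0)) / X.std(0)
        F, stats = build_interaction_features(X, [(0, 1), (2, 4)],
                                              column_names=list("abcde"))
        assert list(F.columns) == ["a:b", "c:e"]
        assert np.abs(F.values.mean(axis=0)).max() < 1e-10
        assert np.abs(F.values.std(axis=0) - 1.0).max() < 1e-10

    def test_self_pair_rejected(self):
        X = np.random.default_rng(0).standard_normal((10, 3))
        with pytest.raises(ValueError, match="self-pair"):
            build_interaction_features(X, [(1, 1)])

    def test_test_data_uses_training_statistics(self):
        rng = np.random.default_rng(3)
        Xtr = rng.standard_normal((100, 4))
        Xte = rng.standard_normal((50, 4))
        _, stats = build_interaction_features(Xtr, [(0, 1)])
        Fte, _ = build_interaction_features(Xte, [(0, 1)], stats=stats)
        expected = (Xte[:, 0] * Xte[:, 1] - stats[0][0]) / stats[1][0]
        np.testing.assert_allclose(Fte.values.ravel(), expected)


class TestIO:
    def test_round_trip(self, tmp_path):
        sc = SimulationScenario(setting=1, pattern="within", n_train=30,
                                n_test=10, seed=1)
        coll = setting_collection(1)
        truth = make_true_model(sc, coll, expand(coll))
        X = make_covariates(30, coll.q, 0.5, seed=2)
        ds = simulate_survival(X, truth, seed=3, tau=0.02)
        e, s, j = (tmp_path / "e.tsv", tmp_path / "s.tsv", tmp_path / "m.json")
        write_dataset(ds, e, s, j)
        back = read_dataset(e, s)
        np.testing.assert_allclose(back.X.values, ds.X.values)
        np.testing.assert_allclose(back.time, ds.time)
        np.testing.assert_array_equal(back.status, ds.status)
        assert j.exists()

    def test_setting2_overlap_bookkeeping(self):
        sizes, overlaps = CHAIN_SPECS[2]
        assert sum(sizes) - sum(overlaps) == 462
        assert len(overlaps) == len(sizes) - 1
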