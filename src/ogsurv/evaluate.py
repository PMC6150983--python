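"""Performance measures for selection, estimation and survival prediction.

Measures mirror the simulation study's reporting: RMSE of the coefficient
vector over the full main+pair feature universe, inclusion indicators
(T.model, Tint.model), sensitivity/specificity of selection, selected model
size, test-set partial-likelihood deviance against the null, Harrell's
c-index of the prognostic index (PI), the Wald p-value of PI in a
univariate Cox model on test data, and log-rank tests across PI-defined
prognosis groups (median split, and tertiles).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict
from itertools import combinations

import numpy as np
import pandas as pd

from . import cox
from .estimators import (OracleCox, OrdinaryLassoCox, OverlapGroupLassoCox,
                         OverlappingGroupScreeningCox, UnivariateSelectionCox,
                         pair_name)
from .simulate import (SimulationScenario, SurvivalDataset, TrueModel,
                       calibrate_censoring_tau, make_dataset, setting_collection)
from .util import check_survival_y, spawn_seeds

logger = logging.getLogger(__name__)


def rmse(beta_hat, beta_true) -> float:
    """Root mean squared error over the full model's coordinate system.

    Both vectors must already be embedded in the same S-dimensional
    feature universe (unselected coefficients zero); S is their length.
    """
    beta_hat = np.asarray(beta_hat, dtype=float).ravel()
    beta_true = np.asarray(beta_true, dtype=float).ravel()
    if beta_hat.size != beta_true.size:
        raise ValueError("coefficient vectors differ in length")
    return float(np.sqrt(np.mean((beta_true - beta_hat) ** 2)))


@dataclass
class SelectionMetrics:
    t_model: int
    tint_model: int
    sensitivity: float
    specificity: float
    s_model: int


def selection_metrics(selected, true_main, true_int, universe_size: int) -> SelectionMetrics:
    """Inclusion and sensitivity/specificity of a selected feature set."""
    selected = set(selected)
    true_main = set(true_main)
    true_int = set(true_int)
    truth = true_main | true_int
    n_true = len(truth)
    n_untrue = universe_size - n_true
    hit = len(selected & truth)
    false_pos = len(selected) - hit
    return SelectionMetrics(
        t_model=int(truth <= selected),
        tint_model=int(true_int <= selected),
        sensitivity=hit / n_true if n_true else 1.0,
        specificity=(n_untrue - false_pos) / n_untrue if n_untrue else 1.0,
        s_model=len(selected))


def prognosis_index(estimator, X_test) -> np.ndarray:
    """PI = x* beta-hat on test features (training-statistics standardized)."""
    return np.asarray(estimator.predict(X_test), dtype=float)


def c_index(pi, y) -> float:
    """Harrell's concordance of PI with the censored outcome (ties count 1/2)."""
    from sksurv.metrics import concordance_index_censored

    time, status = check_survival_y(y)
    result = concordance_index_censored(status.astype(bool), time,
                                        np.asarray(pi, dtype=float))
    return float(result[0])


def test_deviance(pi, y) -> float:
    """-2 [lpl_test(PI) - lpl_test(0)] under the Breslow partial likelihood.

    Negative values mean the fitted prognostic index beats the null model
    on the test data.
    """
    time, status = check_survival_y(y)
    pi = np.asarray(pi, dtype=float)
    lpl_model = cox.cox_log_partial_likelihood(pi, time, status)
    lpl_null = cox.cox_log_partial_likelihood(np.zeros_like(pi), time, status)
    return float(-2.0 * (lpl_model - lpl_null))


def cox_test(pi, y) -> float:
    """Wald p-value of PI as the sole covariate in a test-data Cox model."""
    time, status = check_survival_y(y)
    pi = np.asarray(pi, dtype=float)
    if np.ptp(pi) == 0:
        warnings.warn("constant prognostic index carries no information; p = 1",
                      RuntimeWarning)
        return 1.0
    from scipy.stats import norm

    z = (pi - pi.mean()) / pi.std()
    fit = cox.fit_cox(z[:, None], (time, status), penalty="none",
                      compute_variance=True)
    se = float(np.sqrt(fit.var_[0, 0]))
    return float(2.0 * norm.sf(abs(fit.coef_[0]) / se))


def logrank_tests(pi, y) -> tuple:
    """Log-rank p-values for PI-defined prognosis groups on test data.

    Two groups split at the median PI and three groups at the tertiles;
    subjects exactly on a boundary go to the lower group.  Returns
    (p_median_split, p_tertile_split); a split that leaves an empty group
    raises.
    """
    from lifelines.statistics import multivariate_logrank_test

    time, status = check_survival_y(y)
    pi = np.asarray(pi, dtype=float)
    if pi.size < 4:
        raise ValueError("need at least 4 subjects for the median split")

    def split_p(cuts):
        grp = np.searchsorted(np.sort(cuts), pi, side="right")
        if len(np.unique(grp)) < len(cuts) + 1:
            raise ValueError("a prognosis group is empty; cannot run the log-rank test")
        res = multivariate_logrank_test(time, grp, status)
        return float(res.p_value)

    p2 = split_p([np.median(pi)])
    if pi.size < 6:
        raise ValueError("need at least 6 subjects for the tertile split")
    p3 = split_p(list(np.quantile(pi, [1 / 3, 2 / 3])))
    return p2, p3


@dataclass
class EvaluationReport:
    """All per-replicate measures for one fitted model."""

    rmse: float
    t_model: int
    tint_model: int
    sensitivity: float
    specificity: float
    s_model: int
    deviance: float
    c_index: float
    cox_test_p: float
    lr_test_p: float
    lr_test3_p: float

    def to_dict(self) -> dict:
        return asdict(self)


def feature_universe(gene_names) -> list:
    """Canonical full universe: all genes then all i<j product features."""
    names = list(gene_names)
    return names + [pair_name(names, i, j)
                    for i, j in combinations(range(len(names)), 2)]


def embed_coefficients(named_coefs: dict, universe: list) -> np.ndarray:
    pos = {n: k for k, n in enumerate(universe)}
    beta = np.zeros(len(universe))
    for name, b in named_coefs.items():
        beta[pos[name]] = b
    return beta


def true_coefficients(truth: TrueModel) -> dict:
    out = {n: b for n, b in zip(truth.gene_names, truth.beta_main) if b != 0.0}
    out.update({n: b for n, b in zip(truth.interaction_feature_names(),
                                     truth.beta_int)})
    return out


def evaluate_model(estimator, truth: TrueModel, test: SurvivalDataset,
                   universe: list | None = None) -> EvaluationReport:
    """Score one fitted estimator against the truth and a test cohort."""
    if universe is None:
        universe = feature_universe(truth.gene_names)
    beta_true = embed_coefficients(true_coefficients(truth), universe)
    beta_hat = embed_coefficients(estimator.coef_named_(), universe)
    sel = selection_metrics(estimator.selected_features_,
                            truth.main_feature_names(),
                            truth.interaction_feature_names(),
                            len(universe))
    pi = prognosis_index(estimator, test.X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ct = cox_test(pi, test.y)
        try:
            p2, p3 = logrank_tests(pi, test.y)
        except ValueError:
            p2, p3 = np.nan, np.nan
    return EvaluationReport(
        rmse=rmse(beta_hat, beta_true),
        t_model=sel.t_model, tint_model=sel.tint_model,
        sensitivity=sel.sensitivity, specificity=sel.specificity,
        s_model=sel.s_model,
        deviance=test_deviance(pi, test.y),
        c_index=c_index(pi, test.y),
        cox_test_p=ct, lr_test_p=p2, lr_test3_p=p3)


METHODS = ("oracle", "ogs-lasso", "ogs-ridge", "uni-sel", "ordinary-lasso",
           "overlap-lasso")


def _fit_method(method: str, train: SurvivalDataset, truth: TrueModel,
                collection, seed: int):
    if method == "oracle":
        return OracleCox(true_model=truth).fit(train.X, train.y)
    if method == "ogs-lasso":
        return OverlappingGroupScreeningCox(
            pathways=collection, penalty="lasso",
            random_state=seed).fit(train.X, train.y)
    if method == "ogs-ridge":
        return OverlappingGroupScreeningCox(
            pathways=collection, penalty="ridge",
            random_state=seed).fit(train.X, train.y)
    if method == "uni-sel":
        return UnivariateSelectionCox().fit(train.X, train.y)
    if method == "ordinary-lasso":
        return OrdinaryLassoCox(random_state=seed).fit(train.X, train.y)
    if method == "overlap-lasso":
        return OverlapGroupLassoCox(pathways=collection,
                                    random_state=seed).fit(train.X, train.y)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


#: row labels and the statistic aggregated over replicates
_SUMMARY_SPEC = [("RMSE.M", "rmse", "median"), ("T.model", "t_model", "mean"),
                 ("Tint.model", "tint_model", "mean"),
                 ("Sen.", "sensitivity", "mean"),
                 ("Spe.", "specificity", "mean"),
                 ("S.model", "s_model", "median"),
                 ("Deviance", "deviance", "median"),
                 ("c-index", "c_index", "median")]


@dataclass
class TableResult:
    scenario: SimulationScenario
    methods: list
    summary: pd.DataFrame            # rows = measures, columns = methods
    per_rep: pd.DataFrame            # one row per (replicate, method)
    extras: dict


def run_table(scenario: SimulationScenario, methods=("oracle", "ogs-lasso"),
              reps: int = 50, seed: int = 0, progress: bool = False) -> TableResult:
    """Replicate a simulation scenario and aggregate the study-style summary row.

    Per method, medians are reported for RMSE, S.model, deviance and
    c-index, and means (proportions) for T.model, Tint.model, sensitivity
    and specificity.  The censoring bound tau is calibrated once per
    scenario; per-replicate seeds are spawned from ``seed``.
    """
    collection = setting_collection(scenario.setting)
    seeds = spawn_seeds(seed, reps + 1)
    truth0_scenario = SimulationScenario(**{**scenario.__dict__, "seed": seeds[0]})
    train0, _, truth, tau = make_dataset(truth0_scenario)  # calibration pass
    rows = []
    extras: dict = {"tau": tau, "screening": []}
    for r in range(reps):
        rep_scenario = SimulationScenario(**{**scenario.__dict__, "seed": seeds[r + 1]})
        train, test, truth, _ = make_dataset(rep_scenario, tau=tau)
        universe = feature_universe(truth.gene_names)
        for method in methods:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                est = _fit_method(method, train, truth, collection, seeds[r + 1])
                rep = evaluate_model(est, truth, test, universe)
            row = {"rep": r, "method": method, **rep.to_dict()}
            rows.append(row)
            if hasattr(est, "screening_"):
                extras["screening"].append(
                    {"rep": r, "method": method,
                     "m_main": est.screening_.m_main,
                     "m_int": est.screening_.m_int,
                     "c_int": est.screening_.c_int,
                     "p_values": list(est.screening_.interaction_pvalues)})
        if progress:
            logger.info("replicate %d/%d done", r + 1, reps)
    per_rep = pd.DataFrame(rows)
    summary = {}
    for method in methods:
        sub = per_rep[per_rep["method"] == method]
        col = {}
        for label, fieldname, how in _SUMMARY_SPEC:
            vals = sub[fieldname].astype(float)
            col[label] = float(vals.median() if how == "median" else vals.mean())
        summary[method] = col
    summary = pd.DataFrame(summary)
    return TableResult(scenario=scenario, methods=list(methods),
                       summary=summary, per_rep=per_rep, extras=extras)
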