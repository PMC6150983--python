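"""Estimators for survival prediction from pathway-structured expression data.

The centrepiece is :class:`OverlappingGroupScreeningCox`, the four-step
overlapping group screening (OGS) procedure:

1. overlapping-group-lasso Cox on the latent (duplicated-column) design to
   select causal pathways M_main;
2. SKAT tests of every pathway-interaction group implied by M_main;
3. a permutation-derived cutoff C_int — the smallest SKAT p-value observed
   across all groups on row-permuted expression data — with groups selected
   when their observed p-value falls strictly below it;
4. a ridge- or lasso-penalized Cox model on the candidate main effects and
   candidate gene-pair products.

Comparators with the same fit/predict surface: :class:`OracleCox` (the true
model's support), :class:`UnivariateSelectionCox` (per-feature Cox tests
with Benjamini-Hochberg FDR control), :class:`OrdinaryLassoCox` (lasso over
all mains and pairs) and :class:`OverlapGroupLassoCox` (Step 1 alone, no
interactions).  ``predict`` returns the prognostic index (PI), the linear
predictor on test features standardized with training statistics; higher
PI means higher hazard.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.preprocessing import StandardScaler
from statsmodels.stats.multitest import multipletests

from . import cox
from .cox import _CoxPrep  # noqa: F401  (shared Breslow scaffolding)
from .pathways import PathwayCollection, apply_unmapped_policy, collapse, expand
from .skat import (CoxSkatNull, InteractionGroup, enumerate_interaction_groups,
                   skat_test, standardized_products)
from .simulate import SurvivalDataset, TrueModel
from .util import as_structured_y, check_survival_y, spawn_seeds

logger = logging.getLogger(__name__)


@dataclass
class ScreeningResult:
    """Outcome of OGS Steps 1-3."""

    m_main: list                     # selected pathway indices
    pathway_names: list
    groups: list                     # enumerated InteractionGroups
    interaction_pvalues: np.ndarray  # observed p_b, b = 1..B
    permuted_pvalues: np.ndarray     # null p*_b (B * n_perm values)
    c_int: float
    m_int: list                      # selected group ids
    candidate_genes: list            # gene (column) names
    candidate_pairs: list            # (i, j) column indices, i < j

    @property
    def A(self) -> int:
        return len(self.m_main)

    @property
    def B(self) -> int:
        return len(self.groups)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        sel = set(self.m_int)
        for g, p in zip(self.groups, self.interaction_pvalues):
            rows.append({"group": g.gid, "kind": g.kind,
                         "pathway_a": self.pathway_names[g.source_pathways[0]],
                         "pathway_b": self.pathway_names[g.source_pathways[1]],
                         "l": g.l, "p_value": p, "selected": g.gid in sel})
        return pd.DataFrame(rows)


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{j + 1}" for j in range(X.shape[1])])


def pair_name(names, i, j) -> str:
    return f"{names[i]}:{names[j]}"


class _BaseSurvivalEstimator(BaseEstimator):
    """Shared standardization, prediction and scoring machinery."""

    def _validate_fit(self, X, y):
        Xf = _as_frame(X)
        time, status = check_survival_y(y, n=len(Xf))
        if status.sum() < 1:
            raise ValueError("no events in the training data")
        self.feature_names_in_ = list(Xf.columns)
        self.n_features_in_ = Xf.shape[1]
        scaler = StandardScaler().fit(Xf.values)
        scaler.scale_[scaler.scale_ == 0] = 1.0
        self.scaler_ = scaler
        return Xf, scaler.transform(Xf.values), time, status

    def _transform(self, X) -> np.ndarray:
        Xf = _as_frame(X)
        if list(Xf.columns) != self.feature_names_in_:
            Xf = Xf[self.feature_names_in_]
        return self.scaler_.transform(Xf.values)

    def _model_features(self, X_std) -> np.ndarray:
        """Design matrix of the fitted model's features; override as needed."""
        idx = self.main_indices_
        mains = X_std[:, idx] if len(idx) else np.empty((len(X_std), 0))
        if self.pair_indices_:
            R, _ = standardized_products(X_std, self.pair_indices_,
                                         stats=self.pair_stats_)
        else:
            R = np.empty((len(X_std), 0))
        return np.hstack([mains, R])

    def predict(self, X) -> np.ndarray:
        """Prognostic index x* beta-hat per test subject."""
        if not hasattr(self, "coef_"):
            raise RuntimeError("estimator is not fitted")
        F = self._model_features(self._transform(X))
        return F @ self.coef_ if F.shape[1] else np.zeros(len(F))

    def score(self, X, y) -> float:
        """Harrell's concordance index of the prognostic index."""
        from .evaluate import c_index
        return c_index(self.predict(X), y)

    @property
    def selected_features_(self) -> list:
        """Names of features with nonzero fitted coefficients."""
        return [n for n, b in zip(self.model_feature_names_, self.coef_)
                if b != 0.0]

    def coef_named_(self) -> dict:
        return dict(zip(self.model_feature_names_, self.coef_))


def _coxnet_cv(F, time, status, n_folds=5, seed=0, n_alphas=30,
               alpha_min_ratio=0.01, tol=5e-6):
    """Lasso Cox path (glmnet-style) with lambda chosen by CV deviance.

    The path solver is scikit-survival's Coxnet; the selection rule is the
    Verweij-Van Houwelingen cross-validated partial likelihood, stratified
    by event status.
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis

    ys = as_structured_y(time, status)
    base = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=n_alphas,
                                  alpha_min_ratio=alpha_min_ratio,
                                  normalize=False, fit_baseline_model=False,
                                  tol=tol)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        base.fit(F, ys)
    alphas = np.asarray(base.alphas_)
    folds = cox._stratified_folds(status, n_folds, seed)
    prep_all = _CoxPrep(time, status)
    F_all = F[prep_all.order]
    dev = np.zeros(len(alphas))
    for train_idx, _ in folds:
        cn = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas,
                                    normalize=False, fit_baseline_model=False,
                                    tol=tol)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cn.fit(F[train_idx], ys[train_idx])
        prep_tr = _CoxPrep(time[train_idx], status[train_idx])
        F_tr = F[train_idx][prep_tr.order]
        fitted = np.asarray(cn.alphas_)
        for i, a in enumerate(alphas):
            k = int(np.argmin(np.abs(fitted - a)))
            beta = cn.coef_[:, k]
            dev[i] += -2.0 * (prep_all.lpl_sorted(F_all @ beta)
                              - prep_tr.lpl_sorted(F_tr @ beta))
    best = int(np.argmin(dev))
    coef = base.coef_[:, best]
    return coef, float(alphas[best]), alphas, dev / len(folds)


class OverlappingGroupScreeningCox(_BaseSurvivalEstimator):
    """Overlapping group screening for genes and gene-gene interactions.

    Parameters
    ----------
    pathways : PathwayCollection
        Prior grouping of the expression columns; pathways may overlap.
        Columns mapped to no pathway are discarded or pooled into an extra
        group according to ``pathways.unmapped_policy``.
    penalty : {"lasso", "ridge"}
        Penalty of the final (Step 4) prediction model.  Lasso may drop
        candidates; ridge retains every candidate.
    n_perm : int
        Permutation replicates for the Step-3 cutoff; the cutoff is the
        minimum null p-value over all groups and replicates.
    cv : int
        Folds for every internal cross-validation.
    weight_ridge : "cv" or float
        Ridge penalty for the SKAT weight fits.
    standardize : bool
        Standardize columns on training statistics (recommended; the
        procedure is defined on standardized predictors).
    random_state : int
        Master seed; all internal randomness (CV folds, the permutation)
        is spawned from it.

    Attributes
    ----------
    screening_ : ScreeningResult
    coef_ : ndarray of the final model's coefficients
    model_feature_names_ : names of the final model's features
    """

    def __init__(self, pathways: PathwayCollection = None, penalty: str = "lasso",
                 n_perm: int = 1, cv: int = 5, weight_ridge="cv",
                 perm_weights: str = "reuse", n_lambda: int = 100,
                 lambda_min_ratio: float = 0.001, standardize: bool = True,
                 random_state: int = 0):
        self.pathways = pathways
        self.penalty = penalty
        self.n_perm = n_perm
        self.cv = cv
        self.weight_ridge = weight_ridge
        self.perm_weights = perm_weights
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.standardize = standardize
        self.random_state = random_state

    # -- steps -------------------------------------------------------------
    def _step1(self, X_std, y, gene_idx, seed):
        expansion = self.expansion_
        cols = np.fromiter((gene_idx[g] for g in expansion.gene_universe),
                           dtype=np.intp)
        X_lat = X_std[:, cols[expansion.gene_of]]
        groups = expansion.latent_group_of
        sel = cox.cv_select_lambda(X_lat, y, penalty="group_lasso", groups=groups,
                                   n_folds=self.cv, seed=seed,
                                   grid_size=self.n_lambda,
                                   min_ratio=self.lambda_min_ratio, tol=1e-7)
        fit = cox.fit_cox(X_lat, y, penalty="group_lasso", lam=sel.lam,
                          groups=groups, tol=1e-8)
        norms = np.array([np.linalg.norm(fit.coef_[sl])
                          for sl in expansion.group_slices()])
        m_main = [g for g in range(len(norms)) if norms[g] > 0]
        self.step1_model_ = fit
        self.step1_lambda_ = sel.lam
        return m_main

    def fit(self, X, y):
        if self.pathways is None:
            raise ValueError("a PathwayCollection is required")
        if self.penalty not in ("lasso", "ridge"):
            raise ValueError("final penalty must be 'lasso' or 'ridge'")
        Xf, X_std, time, status = self._validate_fit(X, y)
        if not self.standardize:
            X_std = Xf.values.astype(float)
        names = self.feature_names_in_
        yv = (time, status)
        s_step1, s_perm, s_weights, s_final = spawn_seeds(self.random_state, 4)
        rng = np.random.default_rng(s_perm)

        self.collection_ = apply_unmapped_policy(self.pathways, names)
        self.expansion_ = expand(self.collection_)
        gene_idx = {g: i for i, g in enumerate(names)}

        m_main = self._step1(X_std, yv, gene_idx, s_step1)
        if not m_main:
            warnings.warn("Step 1 selected no pathway; returning a null model",
                          RuntimeWarning)
            self.screening_ = ScreeningResult(
                m_main=[], pathway_names=list(self.collection_.names), groups=[],
                interaction_pvalues=np.empty(0), permuted_pvalues=np.empty(0),
                c_int=np.nan, m_int=[], candidate_genes=[], candidate_pairs=[])
            self.main_indices_ = []
            self.pair_indices_ = []
            self.pair_stats_ = None
            self.model_feature_names_ = []
            self.coef_ = np.empty(0)
            self.final_model_ = None
            return self

        # map collection gene names to data column indices
        to_col = {g: gene_idx[g] for g in self.collection_.gene_universe}
        groups_enum = enumerate_interaction_groups(self.collection_, m_main)
        col_of_univ = np.fromiter(
            (to_col[g] for g in self.collection_.gene_universe), dtype=np.intp)

        def column_pairs(g: InteractionGroup):
            pairs = [(col_of_univ[i], col_of_univ[j]) for i, j in g.pairs]
            return [(min(i, j), max(i, j)) for i, j in pairs]

        null = CoxSkatNull(yv)
        w_seeds = spawn_seeds(s_weights, (1 + self.n_perm) * len(groups_enum))
        p_obs = np.empty(len(groups_enum))
        Rs, obs_weights = [], []
        for b, g in enumerate(groups_enum):
            R, _ = standardized_products(X_std, column_pairs(g))
            Rs.append(R)
            res = skat_test(R, null=null, ridge_lambda=self.weight_ridge,
                            seed=w_seeds[b])
            obs_weights.append(res.weights)
            p_obs[b] = res.p_value
        # Step 3: permute subjects' expression rows to break the association
        p_null = np.empty(len(groups_enum) * self.n_perm)
        for t in range(self.n_perm):
            perm = rng.permutation(len(X_std))
            for b, R in enumerate(Rs):
                if self.perm_weights == "reuse":
                    res = skat_test(R[perm], null=null, weights=obs_weights[b])
                else:
                    res = skat_test(R[perm], null=null,
                                    ridge_lambda=self.weight_ridge,
                                    seed=w_seeds[len(groups_enum) * (t + 1) + b])
                p_null[t * len(groups_enum) + b] = res.p_value
        c_int = float(p_null.min())
        m_int = [g.gid for g, p in zip(groups_enum, p_obs) if p < c_int]

        cand_cols = sorted({to_col[g] for a in m_main
                            for g in self.collection_.members[a]})
        cand_pairs = sorted({p for g in groups_enum if g.gid in m_int
                             for p in column_pairs(g)})
        self.screening_ = ScreeningResult(
            m_main=m_main, pathway_names=list(self.collection_.names),
            groups=groups_enum, interaction_pvalues=p_obs,
            permuted_pvalues=p_null, c_int=c_int, m_int=m_int,
            candidate_genes=[names[c] for c in cand_cols],
            candidate_pairs=cand_pairs)

        # Step 4: penalized Cox on candidates
        self.main_indices_ = cand_cols
        self.pair_indices_ = cand_pairs
        if cand_pairs:
            R_cand, self.pair_stats_ = standardized_products(X_std, cand_pairs)
        else:
            R_cand, self.pair_stats_ = np.empty((len(X_std), 0)), None
        F = np.hstack([X_std[:, cand_cols], R_cand])
        self.model_feature_names_ = ([names[c] for c in cand_cols]
                                     + [pair_name(names, i, j) for i, j in cand_pairs])
        if self.penalty == "lasso":
            coef, lam, _, _ = _coxnet_cv(F, time, status, n_folds=self.cv,
                                         seed=s_final)
            self.final_model_ = cox.FittedCoxModel(
                coef_=coef, penalty="lasso", lam=lam, converged=True,
                log_partial_likelihood=cox.cox_log_partial_likelihood(
                    F @ coef, time, status),
                n_iter=-1, feature_names=self.model_feature_names_)
        else:
            sel = cox.cv_select_lambda(F, yv, penalty="ridge", n_folds=self.cv,
                                       seed=s_final,
                                       grid=np.geomspace(100.0, 1e-3, 20))
            self.final_model_ = cox.fit_cox(F, yv, penalty="ridge", lam=sel.lam,
                                            feature_names=self.model_feature_names_)
        self.coef_ = self.final_model_.coef_
        return self


class OracleCox(_BaseSurvivalEstimator):
    """Unpenalized Cox fit on the true support (known only in simulations).

    Near-separable data (very strong effects) may defeat the unpenalized
    fit; a tiny ridge stabilizer (lambda = 1e-4) is then applied with a
    warning.
    """

    def __init__(self, true_model: TrueModel = None, standardize: bool = True):
        self.true_model = true_model
        self.standardize = standardize

    def fit(self, X, y):
        if self.true_model is None:
            raise ValueError("OracleCox requires the true model")
        Xf, X_std, time, status = self._validate_fit(X, y)
        names = self.feature_names_in_
        idx = {g: i for i, g in enumerate(names)}
        self.main_indices_ = [idx[g] for g in self.true_model.main_feature_names()]
        self.pair_indices_ = [tuple(sorted(p)) for p in self.true_model.interaction_pairs]
        R, self.pair_stats_ = standardized_products(X_std, self.pair_indices_) \
            if self.pair_indices_ else (np.empty((len(X_std), 0)), None)
        F = np.hstack([X_std[:, self.main_indices_], R])
        self.model_feature_names_ = ([names[c] for c in self.main_indices_]
                                     + [pair_name(names, i, j)
                                        for i, j in self.pair_indices_])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = cox.fit_cox(F, (time, status), penalty="none")
        if not fit.converged:
            warnings.warn("oracle fit near separation; adding ridge 1e-4",
                          RuntimeWarning)
            fit = cox.fit_cox(F, (time, status), penalty="ridge", lam=1e-4)
        self.final_model_ = fit
        self.coef_ = fit.coef_
        return self


def _full_universe(X_std, names, block: int = 4096):
    """Iterate (name_list, column_block) over all mains then all pairs."""
    q = X_std.shape[1]
    yield [names[j] for j in range(q)], X_std
    pairs = list(combinations(range(q), 2))
    for s in range(0, len(pairs), block):
        chunk = pairs[s:s + block]
        R, _ = standardized_products(X_std, chunk)
        yield [pair_name(names, i, j) for i, j in chunk], R


def _univariate_cox_stats(F, time, status, n_iter: int = 15):
    """Vectorized per-feature Cox fits: coefficients and Wald p-values."""
    from scipy.stats import norm

    prep = _CoxPrep(time, status)
    Fs = F[prep.order]
    n, p = Fs.shape
    d = prep.d[:, None]
    rs = prep.rs
    cum_idx = prep.cum_idx
    delta = prep.status_s.astype(float)[:, None]
    b = np.zeros(p)
    H = np.ones(p)
    for _ in range(n_iter):
        eta = Fs * b
        c = eta.max(axis=0)
        r = np.exp(eta - c)
        rcs = np.cumsum(r[::-1], axis=0)[::-1]
        s0 = rcs[rs]
        a = d / s0
        cum = np.vstack([np.zeros(p), np.cumsum(a, axis=0)])[cum_idx]
        ehat = r * cum
        grad = (Fs * (delta - ehat)).sum(axis=0)
        rx = r * Fs
        s1 = np.cumsum(rx[::-1], axis=0)[::-1][rs]
        s2 = np.cumsum((rx * Fs)[::-1], axis=0)[::-1][rs]
        mu = s1 / s0
        H = (d * (s2 / s0 - mu * mu)).sum(axis=0)
        H = np.maximum(H, 1e-12)
        step = np.clip(grad / H, -2.0, 2.0)
        b = b + step
        if np.max(np.abs(grad) / (H + 1.0)) < 1e-10:
            break
    z = np.abs(b) * np.sqrt(H)
    pvals = 2.0 * norm.sf(z)
    return b, pvals


class UnivariateSelectionCox(_BaseSurvivalEstimator):
    """Per-feature Cox screening over all mains and pairs with BH FDR control.

    Features surviving Benjamini-Hochberg at the given FDR level are refit
    jointly by unpenalized Cox (ridge-stabilized when the survivors exceed
    n/2).  No survivor yields an intercept-only (all-zero) model.
    """

    def __init__(self, fdr: float = 0.05, standardize: bool = True):
        self.fdr = fdr
        self.standardize = standardize

    def fit(self, X, y):
        Xf, X_std, time, status = self._validate_fit(X, y)
        names = self.feature_names_in_
        all_names, pvals, coefs = [], [], []
        for block_names, block in _full_universe(X_std, names):
            b, p = _univariate_cox_stats(block, time, status)
            all_names += block_names
            pvals.append(p)
            coefs.append(b)
        pvals = np.concatenate(pvals)
        reject, _, _, _ = multipletests(pvals, alpha=self.fdr, method="fdr_bh")
        surv = np.flatnonzero(reject)
        self.univariate_pvalues_ = pd.Series(pvals, index=all_names)
        q = X_std.shape[1]
        pair_list = list(combinations(range(q), 2))
        self.main_indices_ = [int(k) for k in surv if k < q]
        self.pair_indices_ = [pair_list[k - q] for k in surv if k >= q]
        self.model_feature_names_ = [all_names[k] for k in surv]
        if not len(surv):
            self.pair_stats_ = None
            self.coef_ = np.empty(0)
            self.final_model_ = None
            return self
        R, self.pair_stats_ = standardized_products(X_std, self.pair_indices_) \
            if self.pair_indices_ else (np.empty((len(X_std), 0)), None)
        F = np.hstack([X_std[:, self.main_indices_], R])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            if len(surv) > len(F) / 2:
                fit = cox.fit_cox(F, (time, status), penalty="ridge", lam=1e-4)
            else:
                fit = cox.fit_cox(F, (time, status), penalty="none")
                if not fit.converged:
                    fit = cox.fit_cox(F, (time, status), penalty="ridge", lam=1e-4)
        self.final_model_ = fit
        self.coef_ = fit.coef_
        return self


class OrdinaryLassoCox(_BaseSurvivalEstimator):
    """Lasso Cox over the full universe of mains and two-way products."""

    def __init__(self, cv: int = 5, n_lambda: int = 100,
                 lambda_min_ratio: float = 0.001, standardize: bool = True,
                 random_state: int = 0):
        self.cv = cv
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.standardize = standardize
        self.random_state = random_state

    def fit(self, X, y):
        Xf, X_std, time, status = self._validate_fit(X, y)
        names = self.feature_names_in_
        q = X_std.shape[1]
        self.main_indices_ = list(range(q))
        self.pair_indices_ = list(combinations(range(q), 2))
        R, self.pair_stats_ = standardized_products(X_std, self.pair_indices_)
        F = np.hstack([X_std, R])
        self.model_feature_names_ = (list(names)
                                     + [pair_name(names, i, j)
                                        for i, j in self.pair_indices_])
        coef, lam, _, _ = _coxnet_cv(F, time, status, n_folds=self.cv,
                                     seed=self.random_state)
        self.lambda_ = lam
        self.final_model_ = cox.FittedCoxModel(
            coef_=coef, penalty="lasso", lam=lam, converged=True,
            log_partial_likelihood=cox.cox_log_partial_likelihood(
                F @ coef, time, status),
            n_iter=-1, feature_names=self.model_feature_names_)
        self.coef_ = coef
        return self


class OverlapGroupLassoCox(_BaseSurvivalEstimator):
    """Overlapping-group-lasso Cox on genes only (no interaction terms).

    Step 1 of the screening procedure used as a standalone predictor: the
    latent-design group lasso is fit at a CV-chosen penalty and the latent
    coefficients are collapsed back to one coefficient per gene.
    """

    def __init__(self, pathways: PathwayCollection = None, cv: int = 5,
                 n_lambda: int = 100, lambda_min_ratio: float = 0.001,
                 standardize: bool = True, random_state: int = 0):
        self.pathways = pathways
        self.cv = cv
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.standardize = standardize
        self.random_state = random_state

    def fit(self, X, y):
        if self.pathways is None:
            raise ValueError("a PathwayCollection is required")
        Xf, X_std, time, status = self._validate_fit(X, y)
        names = self.feature_names_in_
        yv = (time, status)
        self.collection_ = apply_unmapped_policy(self.pathways, names)
        expansion = expand(self.collection_)
        gene_idx = {g: i for i, g in enumerate(names)}
        cols = np.fromiter((gene_idx[g] for g in expansion.gene_universe),
                           dtype=np.intp)
        X_lat = X_std[:, cols[expansion.gene_of]]
        groups = expansion.latent_group_of
        sel = cox.cv_select_lambda(X_lat, yv, penalty="group_lasso",
                                   groups=groups, n_folds=self.cv,
                                   seed=self.random_state,
                                   grid_size=self.n_lambda,
                                   min_ratio=self.lambda_min_ratio, tol=1e-7)
        fit = cox.fit_cox(X_lat, yv, penalty="group_lasso", lam=sel.lam,
                          groups=groups, tol=1e-8)
        beta_gene = collapse(fit.coef_, expansion)
        norms = [np.linalg.norm(fit.coef_[sl]) for sl in expansion.group_slices()]
        self.m_main_ = [g for g, nz in enumerate(norms) if nz > 0]
        self.lambda_ = sel.lam
        self.latent_model_ = fit
        self.main_indices_ = [int(c) for c in cols]
        self.pair_indices_ = []
        self.pair_stats_ = None
        self.model_feature_names_ = [names[c] for c in cols]
        self.coef_ = beta_gene
        self.final_model_ = cox.FittedCoxModel(
            coef_=beta_gene, penalty="group_lasso", lam=sel.lam,
            converged=fit.converged,
            log_partial_likelihood=fit.log_partial_likelihood,
            n_iter=fit.n_iter, feature_names=self.model_feature_names_)
        return self


# ---------------------------------------------------------------------------
# thin functional wrappers over the estimators
# ---------------------------------------------------------------------------

def run_ogs(train: SurvivalDataset, collection: PathwayCollection,
            penalty: str = "lasso", n_perm: int = 1, seed: int = 0,
            **kwargs) -> OverlappingGroupScreeningCox:
    est = OverlappingGroupScreeningCox(pathways=collection, penalty=penalty,
                                       n_perm=n_perm, random_state=seed, **kwargs)
    return est.fit(train.X, train.y)


def run_oracle(train: SurvivalDataset, true_model: TrueModel) -> OracleCox:
    return OracleCox(true_model=true_model).fit(train.X, train.y)


def run_univariate_selection(train: SurvivalDataset,
                             fdr_level: float = 0.05) -> UnivariateSelectionCox:
    return UnivariateSelectionCox(fdr=fdr_level).fit(train.X, train.y)


def run_ordinary_lasso(train: SurvivalDataset, seed: int = 0) -> OrdinaryLassoCox:
    return OrdinaryLassoCox(random_state=seed).fit(train.X, train.y)


def run_overlap_lasso(train: SurvivalDataset, collection: PathwayCollection,
                      seed: int = 0) -> OverlapGroupLassoCox:
    return OverlapGroupLassoCox(pathways=collection,
                                random_state=seed).fit(train.X, train.y)


def step3_select_interactions(interaction_pvalues, c_int: float) -> list:
    """M_int = {b : p_b < C_int}; ties at the cutoff are NOT selected."""
    p = np.asarray(interaction_pvalues, dtype=float)
    return [int(b) for b in np.flatnonzero(p < c_int)]


def permutation_cutoff(X_std, y, groups_R, n_perm: int = 1, seed: int = 0,
                       weight_ridge="cv") -> tuple:
    """Step-3 cutoff from whole-row permutations of the expression matrix.

    ``groups_R`` maps group ids to their standardized product matrices.
    Returns (C_int, null p-values).
    """
    rng = np.random.default_rng(seed)
    null = CoxSkatNull(y)
    w_seeds = spawn_seeds(seed, len(groups_R) * max(1, n_perm) + 1)[1:]
    p_null = []
    for t in range(n_perm):
        perm = rng.permutation(len(X_std))
        for b, R in enumerate(groups_R):
            res = skat_test(np.asarray(R)[perm], null=null,
                            ridge_lambda=weight_ridge,
                            seed=w_seeds[t * len(groups_R) + b])
            p_null.append(res.p_value)
    p_null = np.asarray(p_null)
    return float(p_null.min()), p_null
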