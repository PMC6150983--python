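"""Cox partial-likelihood machinery with Breslow tie handling.

Everything downstream (pathway screening, SKAT, the final prediction
models) runs through this module: penalized fits, the Breslow baseline
hazard, martingale residuals from the null model, and the null covariance
V = diag(e) - P P' of the residual vector used by the SKAT statistic.

Penalized objectives are on the mean scale,

    minimize  -lpl(beta)/n + penalty(lambda, beta),

with penalty ``0.5 * lambda * ||beta||^2`` (ridge), ``lambda * ||beta||_1``
(lasso) or ``lambda * sum_g w_g ||beta_g||_2`` (group lasso,
``w_g = sqrt(|g|)`` by default), so that ``lambda`` is comparable across
cross-validation folds of unequal size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .util import check_survival_y

logger = logging.getLogger(__name__)

PENALTIES = ("none", "ridge", "lasso", "group_lasso")


class _CoxPrep:
    """Sorted-order scaffolding for Breslow partial-likelihood sums.

    Subjects are sorted by observed time; risk-set sums become suffix
    cumulative sums.  All exponentials are computed relative to max(eta)
    so arbitrarily large linear predictors stay finite.
    """

    def __init__(self, time, status):
        time = np.asarray(time, dtype=float).ravel()
        status = np.asarray(status).astype(int).ravel()
        if status.sum() < 1:
            raise ValueError("no events in the survival data")
        self.n = time.size
        self.order = np.argsort(time, kind="stable")
        self.inv_order = np.empty(self.n, dtype=np.intp)
        self.inv_order[self.order] = np.arange(self.n)
        self.time_s = time[self.order]
        self.status_s = status[self.order]
        ev = self.status_s == 1
        ev_times = self.time_s[ev]
        self.te = np.unique(ev_times)                      # distinct event times
        self.v = self.te.size
        self.rs = np.searchsorted(self.time_s, self.te, side="left")
        self.d = (np.searchsorted(ev_times, self.te, side="right")
                  - np.searchsorted(ev_times, self.te, side="left")).astype(float)
        # index of the last event time <= each subject's observed time
        self.cum_idx = np.searchsorted(self.te, self.time_s, side="right")
        self.event_mask_s = ev

    # -- core quantities, all in sorted order ------------------------------
    def _shifted(self, eta_s):
        c = float(np.max(eta_s))
        r = np.exp(eta_s - c)
        s0 = np.cumsum(r[::-1])[::-1][self.rs]             # S0_k * e^{-c}
        return c, r, s0

    def lpl_sorted(self, eta_s) -> float:
        c, r, s0 = self._shifted(eta_s)
        return float(eta_s[self.event_mask_s].sum() - np.dot(self.d, np.log(s0) + c))

    def lpl_resid_sorted(self, eta_s):
        """Log partial likelihood and martingale residuals delta - e."""
        c, r, s0 = self._shifted(eta_s)
        lpl = float(eta_s[self.event_mask_s].sum() - np.dot(self.d, np.log(s0) + c))
        a = np.concatenate(([0.0], np.cumsum(self.d / s0)))
        ehat = r * a[self.cum_idx]                         # w_i * Lambda0(t_i)
        return lpl, self.status_s - ehat, ehat

    def hazard_pieces_sorted(self, eta_s):
        """Cumulative hazards e, increments (shifted scale) and shift c."""
        c, r, s0 = self._shifted(eta_s)
        a = self.d / s0                                    # dLambda_k * e^{c}
        ehat = r * np.concatenate(([0.0], np.cumsum(a)))[self.cum_idx]
        return ehat, a, c, r

    def hessian_sorted(self, eta_s, Xs):
        """Observed information X' V X with V = diag(e) - P P' (sorted order)."""
        ehat, a, c, r = self.hazard_pieces_sorted(eta_s)
        wX = r[:, None] * Xs
        suff = np.cumsum(wX[::-1], axis=0)[::-1]
        B = a[:, None] * suff[self.rs]                     # P' X, v x p
        H = Xs.T @ (ehat[:, None] * Xs) - B.T @ B
        return H, ehat

    def p_matrix_sorted(self, eta_s):
        """Explicit N x v matrix P with p_ik = w_i dLambda_k 1{t_i >= t_(k)}."""
        ehat, a, c, r = self.hazard_pieces_sorted(eta_s)
        at_risk = self.time_s[:, None] >= self.te[None, :]
        P = (r[:, None] * a[None, :]) * at_risk
        return P, ehat


@dataclass
class BaselineHazard:
    """Breslow baseline hazard: increments at distinct event times."""

    event_times: np.ndarray
    increments: np.ndarray

    def cumulative_at(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.event_times, t, side="right")
        cum = np.concatenate(([0.0], np.cumsum(self.increments)))
        return cum[idx]


@dataclass
class FittedCoxModel:
    coef_: np.ndarray
    penalty: str
    lam: float
    converged: bool
    log_partial_likelihood: float
    n_iter: int
    groups: np.ndarray | None = None
    feature_names: list | None = None
    objective_path: list = field(default_factory=list)
    var_: np.ndarray | None = None

    def linear_predictor(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef_

    @property
    def nonzero_(self) -> np.ndarray:
        return np.flatnonzero(self.coef_ != 0.0)


def cox_log_partial_likelihood(eta, time, status) -> float:
    """Breslow log partial likelihood of a fixed linear predictor."""
    prep = _CoxPrep(time, status)
    return prep.lpl_sorted(np.asarray(eta, dtype=float)[prep.order])


def baseline_hazard(time, status, eta=None) -> BaselineHazard:
    """Breslow (Nelson-Aalen when ``eta`` is absent) baseline increments."""
    prep = _CoxPrep(time, status)
    eta_s = np.zeros(prep.n) if eta is None else np.asarray(eta, dtype=float)[prep.order]
    _, a, c, _ = prep.hazard_pieces_sorted(eta_s)
    return BaselineHazard(prep.te.copy(), a * np.exp(-c))


def cumulative_hazards(time, status, eta=None) -> np.ndarray:
    """Per-subject cumulative hazard e_i = w_i * Lambda0(t_i), original order."""
    prep = _CoxPrep(time, status)
    eta_s = np.zeros(prep.n) if eta is None else np.asarray(eta, dtype=float)[prep.order]
    ehat, _, _, _ = prep.hazard_pieces_sorted(eta_s)
    return ehat[prep.inv_order]


def martingale_residuals(time, status, confounders=None) -> np.ndarray:
    """Null-model martingale residuals m_i = delta_i - e_i.

    With ``confounders`` given, the null model is an unpenalized Cox fit on
    those columns (confounder adjustment); otherwise it is the
    covariate-free null whose baseline is the Nelson-Aalen estimator.
    """
    status_arr = np.asarray(status).astype(int).ravel()
    if confounders is None:
        return status_arr - cumulative_hazards(time, status)
    model = fit_cox(confounders, (time, status), penalty="none")
    eta = model.linear_predictor(confounders)
    return status_arr - cumulative_hazards(time, status, eta)


def null_covariance(time, status, eta=None) -> np.ndarray:
    """V = diag(e) - P P', the null covariance of the martingale residuals."""
    prep = _CoxPrep(time, status)
    eta_s = np.zeros(prep.n) if eta is None else np.asarray(eta, dtype=float)[prep.order]
    P, ehat = prep.p_matrix_sorted(eta_s)
    V = np.diag(ehat) - P @ P.T
    inv = prep.inv_order
    return V[np.ix_(inv, inv)]


# ---------------------------------------------------------------------------
# penalized fitting
# ---------------------------------------------------------------------------

def _group_layout(p, groups, group_weights):
    """Contiguity-order bookkeeping for group penalties."""
    if groups is None:
        labels = np.arange(p)
    else:
        labels = np.asarray(groups)
    uniq, inv = np.unique(labels, return_inverse=True)
    order = np.argsort(inv, kind="stable")
    starts = np.searchsorted(np.sort(inv), np.arange(len(uniq)))
    stops = np.append(starts[1:], p)
    sizes = stops - starts
    if group_weights is None:
        gw = np.sqrt(sizes.astype(float))
    else:
        gw = np.asarray(group_weights, dtype=float)
    return order, starts, stops, gw


def _group_norms(beta, starts, stops):
    sq = np.add.reduceat(beta * beta, starts)
    sq[stops == starts] = 0.0
    return np.sqrt(sq)


def _prox_group(z, thresh, starts, stops):
    """Blockwise soft-thresholding: shrink each group's norm by thresh_g."""
    norms = _group_norms(z, starts, stops)
    scale = np.zeros_like(norms)
    nz = norms > 0
    scale[nz] = np.maximum(0.0, 1.0 - thresh[nz] / norms[nz])
    return z * np.repeat(scale, stops - starts)


def lambda_max(X, y, groups=None, group_weights=None) -> float:
    """Smallest penalty weight that zeroes every coefficient (lasso/group)."""
    time, status = check_survival_y(y)
    X = np.asarray(X, dtype=float)
    prep = _CoxPrep(time, status)
    _, m, _ = prep.lpl_resid_sorted(np.zeros(prep.n))
    score = X[prep.order].T @ m / prep.n
    if groups is None:
        return float(np.max(np.abs(score)))
    order, starts, stops, gw = _group_layout(X.shape[1], groups, group_weights)
    norms = _group_norms(score[order], starts, stops)
    return float(np.max(norms / gw))


def _newton(prep, Xs, lam, beta0, tol, max_iter):
    """Damped Newton for the smooth (none/ridge) objective; monotone."""
    n, p = Xs.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    eta = Xs @ beta

    def objective(eta_s_beta):
        eta_, beta_ = eta_s_beta
        return -prep.lpl_sorted(eta_) / n + 0.5 * lam * float(beta_ @ beta_)

    obj = objective((eta, beta))
    path = [obj]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        _, m, _ = prep.lpl_resid_sorted(eta)
        grad = -(Xs.T @ m) / n + lam * beta
        H, _ = prep.hessian_sorted(eta, Xs)
        H = H / n
        H[np.diag_indices_from(H)] += lam + 1e-10 * (1.0 + np.trace(H) / p)
        try:
            direction = np.linalg.solve(H, -grad)
        except np.linalg.LinAlgError:
            direction = np.linalg.lstsq(H, -grad, rcond=None)[0]
        step = 1.0
        for _ in range(40):
            cand = beta + step * direction
            eta_c = Xs @ cand
            obj_c = objective((eta_c, cand))
            if obj_c <= obj + 1e-4 * step * float(grad @ direction) or obj_c < obj:
                break
            step *= 0.5
        else:
            converged = True  # no descent direction left: at numerical optimum
            break
        beta, eta = cand, eta_c
        rel = abs(obj - obj_c) / max(1.0, abs(obj_c))
        obj = obj_c
        path.append(obj)
        if rel < tol:
            converged = True
            break
    return beta, converged, it, path


def _fista(prep, Xs, lam, starts, stops, gw, beta0, tol, max_iter):
    """FISTA with backtracking and adaptive restart for l1/group penalties."""
    n, p = Xs.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()

    def smooth(eta_s):
        return -prep.lpl_sorted(eta_s) / n

    def smooth_grad(eta_s):
        lpl, m, _ = prep.lpl_resid_sorted(eta_s)
        return -lpl / n, -(Xs.T @ m) / n

    def pen(b):
        return lam * float(gw @ _group_norms(b, starts, stops))

    t = 1.0 / max(1.0, np.linalg.norm(Xs, ord="fro") ** 2 / (4.0 * n))
    y = beta.copy()
    eta_y = Xs @ y
    obj = smooth(Xs @ beta) + pen(beta)
    path = [obj]
    theta = 1.0
    beta_prev = beta.copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        f_y, g_y = smooth_grad(eta_y)
        while True:
            z = _prox_group(y - t * g_y, t * lam * gw, starts, stops)
            dz = z - y
            eta_z = Xs @ z
            f_z = smooth(eta_z)
            if f_z <= f_y + float(g_y @ dz) + float(dz @ dz) / (2.0 * t) + 1e-12:
                break
            t *= 0.5
        obj_z = f_z + pen(z)
        if obj_z > obj:            # adaptive restart
            theta = 1.0
            y = beta.copy()
            eta_y = Xs @ y
            t *= 0.8
            continue
        theta_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * theta * theta))
        y = z + ((theta - 1.0) / theta_next) * (z - beta)
        eta_y = Xs @ y
        beta_prev, beta = beta, z
        theta = theta_next
        rel = abs(obj - obj_z) / max(1.0, abs(obj_z))
        obj = obj_z
        path.append(obj)
        t *= 1.1
        if rel < tol:
            converged = True
            break
    return beta, converged, it, path


def fit_cox(X, y, penalty: str = "none", lam: float = 0.0, groups=None,
            group_weights=None, beta0=None, tol: float = 1e-8,
            max_iter: int = 10_000, feature_names=None,
            compute_variance: bool = False) -> FittedCoxModel:
    """Fit a (penalized) Cox model by maximizing the Breslow partial likelihood.

    Parameters
    ----------
    X : (n, p) array
        Feature matrix (standardize beforehand for penalized fits).
    y : survival outcome
        Structured array, ``(time, status)`` pair, or n x 2 array.
    penalty : {"none", "ridge", "lasso", "group_lasso"}
    lam : float
        Penalty weight on the mean log-partial-likelihood scale.
    groups : array-like, optional
        Per-column group labels; required iff ``penalty == "group_lasso"``.
    group_weights : array-like, optional
        Per-group penalty weights; defaults to sqrt(group size).
    """
    if penalty not in PENALTIES:
        raise ValueError(f"unknown penalty {penalty!r}")
    if (groups is not None) != (penalty == "group_lasso"):
        raise ValueError("groups must be given iff penalty='group_lasso'")
    time, status = check_survival_y(y)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be 2-D with at least one feature")
    prep = _CoxPrep(time, status)
    n, p = X.shape
    newton_cap = min(max_iter, 200)

    if penalty == "ridge" and p > n:
        # The ridge penalty is rotation invariant and the optimum lies in
        # the row space of X, so fit on the n-column factor Z = U diag(s)
        # of the thin SVD and map back: beta = V theta.
        U, sv, Vt = np.linalg.svd(X, full_matrices=False)
        keep = sv > 1e-12 * sv[0]
        Z = U[:, keep] * sv[keep]
        sub = fit_cox(Z, (time, status), penalty="ridge", lam=lam,
                      beta0=None if beta0 is None else Vt[keep] @ beta0,
                      tol=tol, max_iter=max_iter)
        beta = Vt[keep].T @ sub.coef_
        model = FittedCoxModel(
            coef_=beta, penalty="ridge", lam=float(lam),
            converged=sub.converged,
            log_partial_likelihood=sub.log_partial_likelihood,
            n_iter=sub.n_iter,
            feature_names=list(feature_names) if feature_names is not None else None,
            objective_path=sub.objective_path)
        if compute_variance:
            raise NotImplementedError(
                "variance not available for the reduced wide-ridge fit")
        return model

    if penalty in ("none", "ridge"):
        Xs = X[prep.order]
        beta, converged, n_iter, path = _newton(
            prep, Xs, lam if penalty == "ridge" else 0.0, beta0, tol, newton_cap)
    else:
        if penalty == "lasso":
            order = np.arange(p)
            starts = np.arange(p)
            stops = starts + 1
            gw = np.ones(p)
        else:
            order, starts, stops, gw = _group_layout(p, groups, group_weights)
        Xs = X[prep.order][:, order]
        b0 = None if beta0 is None else np.asarray(beta0, dtype=float)[order]
        beta_ord, converged, n_iter, path = _fista(
            prep, Xs, lam, starts, stops, gw, b0, tol, max_iter)
        beta = np.empty(p)
        beta[order] = beta_ord
        Xs = X[prep.order]

    if not converged:
        warnings.warn(f"Cox fit ({penalty}) did not converge in {n_iter} iterations",
                      RuntimeWarning)
    lpl = prep.lpl_sorted(Xs @ beta)
    model = FittedCoxModel(
        coef_=beta, penalty=penalty, lam=float(lam), converged=converged,
        log_partial_likelihood=lpl, n_iter=n_iter,
        groups=None if groups is None else np.asarray(groups),
        feature_names=list(feature_names) if feature_names is not None else None,
        objective_path=path)
    if compute_variance:
        H, _ = prep.hessian_sorted(Xs @ beta, Xs)
        if penalty == "ridge":
            H[np.diag_indices_from(H)] += lam * n
        try:
            model.var_ = np.linalg.inv(H + 1e-12 * np.eye(p))
        except np.linalg.LinAlgError:
            model.var_ = np.linalg.pinv(H)
    return model


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class LambdaSelection:
    lam: float
    grid: np.ndarray
    cv_deviance: np.ndarray

    def __float__(self):
        return self.lam


def default_grid(lam_max: float, size: int = 100, min_ratio: float = 0.001) -> np.ndarray:
    return np.geomspace(lam_max, lam_max * min_ratio, size)


def _stratified_folds(status, n_folds, seed):
    status = np.asarray(status).astype(int)
    if status.sum() < n_folds:
        raise ValueError("fewer events than folds; cannot stratify")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros_like(status), status))


def cox_path(X, y, penalty, grid, groups=None, group_weights=None,
             tol=1e-8, max_iter=10_000) -> np.ndarray:
    """Warm-started coefficient path over a descending penalty grid."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if penalty == "ridge" and p > n:
        # reduce once (see fit_cox) instead of per grid point
        U, sv, Vt = np.linalg.svd(X, full_matrices=False)
        keep = sv > 1e-12 * sv[0]
        Z = U[:, keep] * sv[keep]
        sub = cox_path(Z, y, "ridge", grid, tol=tol, max_iter=max_iter)
        return sub @ Vt[keep]
    coefs = np.zeros((len(grid), p))
    beta = None
    for i, lam in enumerate(grid):
        model = fit_cox(X, y, penalty=penalty, lam=float(lam), groups=groups,
                        group_weights=group_weights, beta0=beta, tol=tol,
                        max_iter=max_iter)
        beta = model.coef_
        coefs[i] = beta
    return coefs


def cv_select_lambda(X, y, penalty: str, groups=None, group_weights=None,
                     n_folds: int = 5, seed=0, grid=None, grid_size: int = 100,
                     min_ratio: float = 0.001, tol: float = 1e-7,
                     max_iter: int = 10_000) -> LambdaSelection:
    """Pick the grid penalty minimizing cross-validated partial-likelihood deviance.

    Folds are stratified by event status.  The deviance is the
    Verweij-Van Houwelingen cross-validated partial likelihood
    ``-2 * [lpl_all(beta_{-k}) - lpl_{-k}(beta_{-k})]`` summed over folds.
    """
    time, status = check_survival_y(y)
    X = np.asarray(X, dtype=float)
    if grid is None:
        lmax = lambda_max(X, (time, status),
                          groups=groups if penalty == "group_lasso" else None,
                          group_weights=group_weights)
        if penalty == "ridge":
            # anchor the ridge grid at the lasso-scale lambda_max
            lmax = max(lmax, 1e-8)
        grid = default_grid(lmax * (1.0 + 1e-6), grid_size, min_ratio)
    grid = np.asarray(grid, dtype=float)
    folds = _stratified_folds(status, n_folds, seed)
    prep_all = _CoxPrep(time, status)
    X_all_sorted = X[prep_all.order]
    dev = np.zeros(len(grid))
    for train_idx, _ in folds:
        t_tr, s_tr = time[train_idx], status[train_idx]
        if s_tr.sum() < 1:
            raise ValueError("a training fold has zero events")
        coefs = cox_path(X[train_idx], (t_tr, s_tr), penalty, grid,
                         groups=groups, group_weights=group_weights,
                         tol=tol, max_iter=max_iter)
        prep_tr = _CoxPrep(t_tr, s_tr)
        X_tr_sorted = X[train_idx][prep_tr.order]
        for i, beta in enumerate(coefs):
            lpl_all = prep_all.lpl_sorted(X_all_sorted @ beta)
            lpl_tr = prep_tr.lpl_sorted(X_tr_sorted @ beta)
            dev[i] += -2.0 * (lpl_all - lpl_tr)
    best = int(np.argmin(dev))
    return LambdaSelection(float(grid[best]), grid, dev / len(folds))
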