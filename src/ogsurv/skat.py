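"""Variance-component (SKAT) screening of pathway-interaction groups.

After the causal pathways M_main are chosen, every candidate source of
epistasis is organised into groups of gene-pair product features: one
"within" group per causal pathway, one "cross" group per pair of causal
pathways, and one "cross" group per (causal, non-causal) pathway pair —
B = A + C(A,2) + (G - A) * A groups in total.  Each group k is tested
jointly with the score statistic

    Q_k = m' R_k W_k W_k R_k' m,

where m are the martingale residuals of the covariate-free Cox null
model, R_k holds the group's standardized product features, and W_k is a
diagonal weight matrix with entries sqrt(|ridge coefficient|) from a joint
ridge Cox fit of the group.  Under the null, Q_k follows a mixture of 1-df
chi-squares with weights given by the eigenvalues of
Sigma_k = W_k R_k' V R_k W_k, V = diag(e) - P P'.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from . import cox
from .pathways import PathwayCollection
from .quadform import QuadFormPValue, mixture_chisq_pvalue
from .util import check_survival_y

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InteractionGroup:
    """One pathway-interaction group: a set of gene-pair product features."""

    gid: int
    kind: str                       # "within" or "cross"
    source_pathways: tuple          # (a, b) pathway indices; a == b for within
    pairs: tuple                    # ordered (i, j) gene indices, i < j

    @property
    def l(self) -> int:
        return len(self.pairs)


@dataclass
class SkatResult:
    Q: float
    eigenvalues: np.ndarray
    p_value: float
    method: str
    weights: np.ndarray
    ridge_lambda: float = np.nan


def enumerate_interaction_groups(collection: PathwayCollection, m_main) -> list:
    """All pathway-interaction groups implied by the selected pathways.

    ``m_main`` holds 0-based pathway indices.  Within a cross group of two
    overlapping pathways, self-pairs (a gene with itself) are excluded and
    duplicate unordered pairs kept once.
    """
    m_main = sorted(int(a) for a in m_main)
    if not m_main:
        raise ValueError("M_main is empty")
    G = collection.G
    if any(a < 0 or a >= G for a in m_main):
        raise ValueError("pathway index out of range")
    gidx = collection.gene_index()
    member_idx = [sorted(gidx[g] for g in m) for m in collection.members]
    groups: list[InteractionGroup] = []

    def cross_pairs(a, b):
        seen = set()
        for i in member_idx[a]:
            for j in member_idx[b]:
                if i == j:
                    continue
                key = (i, j) if i < j else (j, i)
                seen.add(key)
        return tuple(sorted(seen))

    gid = 0
    for a in m_main:
        pairs = tuple(combinations(member_idx[a], 2))
        groups.append(InteractionGroup(gid, "within", (a, a), pairs))
        gid += 1
    for a, b in combinations(m_main, 2):
        groups.append(InteractionGroup(gid, "cross", (a, b), cross_pairs(a, b)))
        gid += 1
    others = [g for g in range(G) if g not in m_main]
    for a in m_main:
        for b in others:
            groups.append(InteractionGroup(gid, "cross", (a, b), cross_pairs(a, b)))
            gid += 1
    return groups


def expected_group_count(A: int, G: int) -> int:
    """B = A + C(A, 2) + (G - A) * A."""
    return A + A * (A - 1) // 2 + (G - A) * A


def standardized_products(X_std, pairs, stats=None):
    """Columns of elementwise products of standardized genes, re-standardized.

    ``stats`` (means, sds) from training data may be supplied to transform
    test data consistently; they are returned for reuse.
    """
    X_std = np.asarray(X_std, dtype=float)
    pairs = list(pairs)
    for i, j in pairs:
        if i == j:
            raise ValueError("self-pair requested: a gene cannot interact with itself")
    if not pairs:
        return np.empty((X_std.shape[0], 0)), (np.empty(0), np.empty(0))
    ii = np.fromiter((p[0] for p in pairs), dtype=np.intp)
    jj = np.fromiter((p[1] for p in pairs), dtype=np.intp)
    R = X_std[:, ii] * X_std[:, jj]
    if stats is None:
        mean = R.mean(axis=0)
        sd = R.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        stats = (mean, sd)
    mean, sd = stats
    return (R - mean) / sd, stats


class CoxSkatNull:
    """Null-model ingredients shared by every group test on one dataset.

    Holds the martingale residuals m, the covariance V = diag(e) - P P' and
    its symmetric square root (eigenvalues clipped at zero), so that each
    group only pays for its own projection.
    """

    def __init__(self, y, confounders=None):
        time, status = check_survival_y(y)
        self.time, self.status = time, status
        self.n = time.size
        if confounders is None:
            self.m = cox.martingale_residuals(time, status)
            self.V = cox.null_covariance(time, status)
        else:
            model = cox.fit_cox(confounders, (time, status), penalty="none")
            eta = model.linear_predictor(confounders)
            self.m = np.asarray(status, float) - cox.cumulative_hazards(time, status, eta)
            self.V = cox.null_covariance(time, status, eta)
        s, U = np.linalg.eigh(self.V)
        s = np.clip(s, 0.0, None)
        self._U = U
        self._sqrt_s = np.sqrt(s)

    def sigma_eigenvalues(self, R, weights) -> np.ndarray:
        """Eigenvalues of Sigma = W R' V R W, via the smaller congruent form."""
        B = self._sqrt_s[:, None] * (self._U.T @ (R * weights))
        if B.shape[1] <= self.n:
            sig = B.T @ B
        else:
            sig = B @ B.T
        lam = np.linalg.eigvalsh(sig)
        return lam[::-1]


_WEIGHT_GRID = np.geomspace(100.0, 0.01, 8)


def compute_group_weights(R, y, ridge_lambda="cv", n_folds: int = 5, seed=0):
    """SKAT weights sqrt(|beta~|) from a joint ridge Cox fit of the group.

    ``ridge_lambda`` is a float, or ``"cv"`` to pick it by stratified
    5-fold cross-validated partial-likelihood deviance over a short grid;
    groups wider than n/2 features use a fixed lambda of 1 instead (CV over
    such wide ridge fits buys little and costs much).  A failed ridge fit
    falls back to equal unit weights with a warning.
    """
    R = np.asarray(R, dtype=float)
    n, l = R.shape
    try:
        if ridge_lambda == "cv":
            if l > n / 2:
                lam = 1.0
            else:
                sel = cox.cv_select_lambda(R, y, penalty="ridge", n_folds=n_folds,
                                           seed=seed, grid=_WEIGHT_GRID, tol=1e-8)
                lam = sel.lam
        else:
            lam = float(ridge_lambda)
        fit = cox.fit_cox(R, y, penalty="ridge", lam=lam, tol=1e-8)
        if not fit.converged:
            raise RuntimeError("ridge fit did not converge")
        return np.sqrt(np.abs(fit.coef_)), lam
    except (RuntimeError, np.linalg.LinAlgError) as err:
        warnings.warn(f"ridge weight fit failed ({err}); using equal weights",
                      RuntimeWarning)
        return np.ones(l), np.nan


def skat_statistic(m, R, weights) -> float:
    """Q = m' R W W R' m = || W R' m ||^2 >= 0."""
    m = np.asarray(m, dtype=float).ravel()
    R = np.asarray(R, dtype=float)
    w = np.asarray(weights, dtype=float).ravel()
    if R.shape[0] != m.size or R.shape[1] != w.size:
        raise ValueError("dimension mismatch between residuals, R and weights")
    s = w * (R.T @ m)
    return float(s @ s)


def skat_test(R, y=None, null: CoxSkatNull | None = None, weights=None,
              ridge_lambda="cv", seed=0, acc: float = 1e-6) -> SkatResult:
    """Group-specific SKAT test of one interaction group under the Cox null."""
    if null is None:
        if y is None:
            raise ValueError("either y or a CoxSkatNull must be given")
        null = CoxSkatNull(y)
    R = np.asarray(R, dtype=float)
    lam_used = np.nan
    if weights is None:
        weights, lam_used = compute_group_weights(
            R, (null.time, null.status), ridge_lambda=ridge_lambda, seed=seed)
    weights = np.asarray(weights, dtype=float)
    Q = skat_statistic(null.m, R, weights)
    eig = null.sigma_eigenvalues(R, weights)
    res: QuadFormPValue = mixture_chisq_pvalue(Q, np.clip(eig, 0.0, None), acc=acc)
    return SkatResult(Q=Q, eigenvalues=eig, p_value=res.p, method=res.method,
                      weights=weights, ridge_lambda=lam_used)
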