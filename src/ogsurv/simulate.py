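"""Synthetic gene-expression survival data with overlapping pathway structure.

The generator emulates the study conditions under which the screening
method is evaluated: AR(1)-correlated standard-normal expression values
(corr(x_j, x_k) = rho^|j-k|, rho = 0.5), exponential survival times from a
Cox model with constant baseline hazard 0.1, and uniform censoring
U(0, tau) with tau calibrated so that the expected censoring fraction hits
a stated target (50% or 65%).  Two chain-overlap pathway layouts are
built in: Setting 1 (5 pathways, q = 81 genes, u = 105 latent slots) and
Setting 2 (24 pathways, q = 462, u = 594).  Effects are specified as
constant per-pathway latent coefficients plus three two-way interaction
pairs either within one causal pathway, across two pathways, or both.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pathways import PathwayCollection, LatentExpansion, build_chain_structure, collapse, expand
from .util import rng_from, spawn_seeds

logger = logging.getLogger(__name__)

PATTERNS = ("within", "between", "coexist")

#: chain layouts of the two built-in settings: (sizes, consecutive overlaps)
CHAIN_SPECS = {
    1: ((7, 14, 21, 28, 35), (3, 5, 7, 9)),
    2: ((3, 3, 3, 6, 6, 6, 9, 9, 9, 15, 15, 15, 24, 24, 24,
         36, 36, 36, 45, 45, 45, 60, 60, 60),
        (1, 1, 0, 2, 2, 0, 3, 3, 0, 5, 5, 0, 8, 8, 0,
         12, 12, 0, 15, 15, 0, 20, 20)),
}

#: effective pathways (1-based) with their constant latent effects, and the
#: interaction pairs (1-based gene indices) of the "within"/"between" sets
EFFECT_SPECS = {
    1: {
        "pathways": (2, 4),
        "latent_effects": (4.5, -3.0),
        "within_pairs": ((8, 9), (10, 11), (12, 13)),
        "within_effects": (6.0, 6.0, 6.0),
        "between_pairs": ((36, 66), (38, 68), (40, 70)),
        "between_effects": (-6.0, -6.0, -6.0),
    },
    2: {
        "pathways": (1, 7, 13, 19),
        "latent_effects": (4.5, -3.0, -3.0, 1.5),
        "within_pairs": ((22, 23), (24, 25), (26, 27)),
        "within_effects": (4.0, 4.0, 4.0),
        "between_pairs": ((81, 101), (82, 102), (83, 103)),
        "between_effects": (-4.0, -4.0, -4.0),
    },
}


def setting_collection(setting: int) -> PathwayCollection:
    """The chain-overlap pathway collection of a built-in setting."""
    if setting not in CHAIN_SPECS:
        raise ValueError(f"unknown setting {setting!r}; choose 1 or 2")
    sizes, overlaps = CHAIN_SPECS[setting]
    return build_chain_structure(sizes, overlaps)


@dataclass(frozen=True)
class SimulationScenario:
    """Conditions for one simulated cohort."""

    setting: int = 1
    pattern: str = "within"
    censoring_target: float = 0.50
    n_train: int = 500
    n_test: int = 100
    rho: float = 0.5
    baseline_rate: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.setting not in CHAIN_SPECS:
            raise ValueError(f"unknown setting {self.setting!r}")
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}")
        if not 0.0 < self.censoring_target < 1.0:
            raise ValueError("censoring_target must be in (0, 1)")
        if self.n_train < 2 or self.n_test < 2:
            raise ValueError("need at least two subjects per cohort")


@dataclass
class TrueModel:
    """The data-generating coefficients on the gene scale."""

    beta_main: np.ndarray
    interaction_pairs: list          # 0-based (i, j), i < j
    beta_int: np.ndarray
    effective_pathways: list         # 0-based pathway indices
    gene_names: list

    @property
    def n_effective(self) -> int:
        return int(np.count_nonzero(self.beta_main)) + len(self.interaction_pairs)

    def main_feature_names(self) -> list:
        return [self.gene_names[j] for j in np.flatnonzero(self.beta_main)]

    def interaction_feature_names(self) -> list:
        return [f"{self.gene_names[i]}:{self.gene_names[j]}"
                for i, j in self.interaction_pairs]

    def linear_predictor(self, X_raw) -> np.ndarray:
        X_raw = np.asarray(X_raw, dtype=float)
        eta = X_raw @ self.beta_main
        for (i, j), b in zip(self.interaction_pairs, self.beta_int):
            eta = eta + b * X_raw[:, i] * X_raw[:, j]
        return eta


@dataclass
class SurvivalDataset:
    """Expression matrix plus censored survival outcomes."""

    X: pd.DataFrame                  # samples x genes
    time: np.ndarray
    status: np.ndarray
    standardized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float).ravel()
        self.status = np.asarray(self.status).astype(int).ravel()
        if self.X.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if len(self.X) != self.time.size or self.time.size != self.status.size:
            raise ValueError("X, time and status must agree in length")

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def gene_names(self) -> list:
        return list(self.X.columns)

    @property
    def y(self):
        return (self.time, self.status)

    @property
    def censoring_rate(self) -> float:
        return float(1.0 - self.status.mean())


def make_covariates(n: int, q: int, rho: float = 0.5, seed=0) -> np.ndarray:
    """AR(1)-correlated standard-normal covariates, corr(x_j, x_k) = rho^|j-k|.

    Generated by the exact recursion x_j = rho x_{j-1} + sqrt(1-rho^2) z_j,
    so the law is correct for any number of genes.
    """
    if n < 1 or q < 1:
        raise ValueError("n and q must be positive")
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    rng = rng_from(seed)
    Z = rng.standard_normal((n, q))
    X = np.empty((n, q))
    X[:, 0] = Z[:, 0]
    scale = np.sqrt(1.0 - rho * rho)
    for j in range(1, q):
        X[:, j] = rho * X[:, j - 1] + scale * Z[:, j]
    return X


def make_true_model(scenario: SimulationScenario, collection: PathwayCollection,
                    expansion: LatentExpansion) -> TrueModel:
    """Assemble the true coefficients of a scenario on the gene scale.

    Main effects are constant latent coefficients on every slot of each
    effective pathway, collapsed through beta = S gamma; interaction pairs
    follow the scenario's pattern.
    """
    spec = EFFECT_SPECS[scenario.setting]
    sizes, _ = CHAIN_SPECS[scenario.setting]
    if collection.G != len(sizes) or collection.sizes != tuple(sizes):
        raise ValueError("collection does not match the scenario's setting")
    gamma = np.zeros(expansion.u)
    for path_1b, eff in zip(spec["pathways"], spec["latent_effects"]):
        gamma[expansion.latent_group_of == path_1b - 1] = eff
    beta_main = collapse(gamma, expansion)
    pairs, effs = [], []
    if scenario.pattern in ("within", "coexist"):
        pairs += [(i - 1, j - 1) for i, j in spec["within_pairs"]]
        effs += list(spec["within_effects"])
    if scenario.pattern in ("between", "coexist"):
        pairs += [(i - 1, j - 1) for i, j in spec["between_pairs"]]
        effs += list(spec["between_effects"])
    return TrueModel(beta_main=beta_main, interaction_pairs=pairs,
                     beta_int=np.asarray(effs, dtype=float),
                     effective_pathways=[p - 1 for p in spec["pathways"]],
                     gene_names=list(collection.gene_universe))


def calibrate_censoring_tau(true_model: TrueModel, censoring_target: float,
                            rho: float = 0.5, baseline_rate: float = 0.1,
                            seed=0, n_pilot: int = 100_000,
                            tol: float = 0.01) -> float:
    """Upper end tau of the U(0, tau) censoring law hitting the target rate.

    A subject with event time T drawn once is censored with probability
    min(T / tau, 1), so the expected censoring fraction of a pilot sample
    is monotone in tau and the root is found by bisection without
    redrawing.  The pilot uses 1e5 subjects; the achieved expectation is
    within ``tol`` (1%) of the target.
    """
    rng = rng_from(seed)
    q = true_model.beta_main.size
    T = np.empty(n_pilot)
    chunk = max(1, 20_000_000 // max(q, 1))
    done = 0
    while done < n_pilot:
        m = min(chunk, n_pilot - done)
        X = make_covariates(m, q, rho, rng)
        eta = np.clip(true_model.linear_predictor(X), -300, 300)
        T[done:done + m] = rng.exponential(1.0 / (baseline_rate * np.exp(eta)))
        done += m

    def rate(tau):
        with np.errstate(over="ignore"):
            return float(np.mean(np.minimum(T / tau, 1.0)))

    lo, hi = 1e-300, 1.0
    while rate(hi) > censoring_target:
        hi *= 10.0
        if hi > 1e300:
            raise RuntimeError("censoring calibration failed to bracket")
    lo = hi / 10.0 if hi > 1.0 else lo
    while rate(lo) < censoring_target:
        lo /= 10.0
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        r = rate(mid)
        if abs(r - censoring_target) <= 0.25 * tol:
            return float(mid)
        if r > censoring_target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def simulate_survival(X_raw, true_model: TrueModel, baseline_rate: float = 0.1,
                      censoring_target: float = 0.5, seed=0, tau: float | None = None,
                      gene_names=None, max_retries: int = 10) -> SurvivalDataset:
    """Exponential Cox survival with calibrated uniform censoring.

    T_i ~ Exponential(rate = baseline_rate * exp(eta_i)) with eta_i the true
    linear predictor (mains plus pairwise products of the raw covariates);
    C_i ~ U(0, tau); the observed pair is (min(T, C), 1{T <= C}).
    """
    rng = rng_from(seed)
    X_raw = np.asarray(X_raw, dtype=float)
    if X_raw.shape[1] != true_model.beta_main.size:
        raise ValueError("X_raw column count does not match beta_main")
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be positive")
    if tau is None:
        tau = calibrate_censoring_tau(true_model, censoring_target,
                                      baseline_rate=baseline_rate, seed=rng)
    eta = np.clip(true_model.linear_predictor(X_raw), -300, 300)
    rate = baseline_rate * np.exp(eta)
    for attempt in range(max_retries):
        T = rng.exponential(1.0 / rate)
        C = rng.uniform(0.0, tau, size=len(T))
        status = (T <= C).astype(int)
        if status.sum() >= 1:
            break
        warnings.warn("all subjects censored; regenerating", RuntimeWarning)
    else:
        raise RuntimeError("could not generate a dataset with at least one event")
    time = np.minimum(T, C)
    names = (list(gene_names) if gene_names is not None
             else true_model.gene_names)
    X = pd.DataFrame(X_raw, columns=names)
    return SurvivalDataset(X=X, time=time, status=status, standardized=False,
                           meta={"tau": float(tau),
                                 "baseline_rate": baseline_rate,
                                 "censoring_target": censoring_target})


def build_interaction_features(X_std, pairs, column_names=None, stats=None):
    """Re-standardized pairwise product features of standardized genes.

    Returns a DataFrame with columns named ``"gi:gj"`` plus the
    (means, sds) used, for applying the same transform to test data.
    """
    from .skat import standardized_products

    X_arr = X_std.values if isinstance(X_std, pd.DataFrame) else np.asarray(X_std)
    names = (list(X_std.columns) if isinstance(X_std, pd.DataFrame)
             else (list(column_names) if column_names is not None
                   else [f"x{j + 1}" for j in range(X_arr.shape[1])]))
    R, stats = standardized_products(X_arr, pairs, stats=stats)
    cols = [f"{names[i]}:{names[j]}" for i, j in pairs]
    return pd.DataFrame(R, columns=cols, index=getattr(X_std, "index", None)), stats


def interaction_universe_size(q: int) -> int:
    """Number of main plus two-way interaction features: q + C(q, 2)."""
    return q + q * (q - 1) // 2


def make_dataset(scenario: SimulationScenario, tau: float | None = None):
    """Generate one (train, test, truth) triple under a scenario.

    Sub-seeds for covariates, survival and test data are spawned from
    ``scenario.seed`` so replicates are reproducible stream by stream.
    """
    collection = setting_collection(scenario.setting)
    expansion = expand(collection)
    truth = make_true_model(scenario, collection, expansion)
    s_cal, s_xtr, s_ttr, s_xte, s_tte = spawn_seeds(scenario.seed, 5)
    if tau is None:
        tau = calibrate_censoring_tau(truth, scenario.censoring_target,
                                      rho=scenario.rho,
                                      baseline_rate=scenario.baseline_rate,
                                      seed=s_cal)
    q = collection.q
    X_tr = make_covariates(scenario.n_train, q, scenario.rho, s_xtr)
    train = simulate_survival(X_tr, truth, scenario.baseline_rate,
                              scenario.censoring_target, seed=s_ttr, tau=tau)
    X_te = make_covariates(scenario.n_test, q, scenario.rho, s_xte)
    test = simulate_survival(X_te, truth, scenario.baseline_rate,
                             scenario.censoring_target, seed=s_tte, tau=tau)
    for ds in (train, test):
        ds.meta.update({"setting": scenario.setting, "pattern": scenario.pattern,
                        "seed": scenario.seed})
    return train, test, truth, tau


# ---------------------------------------------------------------------------
# on-disk interchange
# ---------------------------------------------------------------------------

def write_dataset(ds: SurvivalDataset, expression_path, survival_path,
                  sidecar_path=None, extra_meta=None) -> None:
    """Write expression and survival tables as TSV (+ JSON sidecar)."""
    X = ds.X.copy()
    X.insert(0, "sample_id", [f"s{i + 1}" for i in range(ds.n)])
    X.to_csv(expression_path, sep="\t", index=False)
    surv = pd.DataFrame({"sample_id": X["sample_id"],
                         "time": ds.time, "status": ds.status})
    surv.to_csv(survival_path, sep="\t", index=False)
    if sidecar_path is not None:
        meta = dict(ds.meta)
        if extra_meta:
            meta.update(extra_meta)
        Path(sidecar_path).write_text(json.dumps(meta, indent=2, default=float))


def read_dataset(expression_path, survival_path) -> SurvivalDataset:
    X = pd.read_csv(expression_path, sep="\t")
    surv = pd.read_csv(survival_path, sep="\t")
    if "sample_id" in X.columns:
        X = X.set_index("sample_id")
    surv = surv.set_index("sample_id") if "sample_id" in surv.columns else surv
    surv = surv.loc[X.index] if surv.index.name == "sample_id" else surv
    return SurvivalDataset(X=X.reset_index(drop=True),
                           time=surv["time"].to_numpy(),
                           status=surv["status"].to_numpy())
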