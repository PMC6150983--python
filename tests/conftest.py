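"""Shared fixtures: small survival datasets and toy pathway structures."""

import numpy as np
import pytest

import ogsurv as og
from ogsurv.pathways import PathwayCollection


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


def simulate_simple_cox(rng, n, beta, rho=0.0, baseline=0.1, cens_upper=None):
    """Plain Cox-exponential data for unit tests (no pathway structure)."""
    q = len(beta)
    X = og.make_covariates(n, q, rho, rng) if rho else rng.standard_normal((n, q))
    eta = X @ np.asarray(beta, dtype=float)
    T = rng.exponential(1.0 / (baseline * np.exp(np.clip(eta, -300, 300))))
    if cens_upper is None:
        C = np.quantile(T, 0.7) * rng.uniform(0.2, 1.8, n)
    else:
        C = rng.uniform(0, cens_upper, n)
    time = np.minimum(T, C)
    status = (T <= C).astype(int)
    return X, time, status


@pytest.fixture()
def small_cox_data():
    rng = np.random.default_rng(7)
    X, time, status = simulate_simple_cox(rng, 150, [1.0, -0.8, 0.0, 0.0, 0.5])
    X = (X - X.mean(0)) / X.std(0)
    return X, time, status


@pytest.fixture(scope="session")
def worked_example_collection():
    """The 4-gene / 4-pathway overlap illustration."""
    return PathwayCollection(
        names=("P1", "P2", "P3", "P4"),
        members=(("g1", "g2"), ("g2", "g3"), ("g1", "g3"), ("g3", "g4")))


@pytest.fixture(scope="session")
def toy_two_pathways():
    """Two disjoint pathways of 6 genes each (genes g1..g12)."""
    return og.build_chain_structure([6, 6], [0])


@pytest.fixture(scope="session")
def setting1_tau():
    """Censoring calibration for the Setting-1 'within' 50% scenario."""
    sc = og.SimulationScenario(setting=1, pattern="within",
                               censoring_target=0.5, seed=0)
    _, _, truth, tau = og.make_dataset(sc)
    return tau
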