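import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

from microstm.io_prep import OtuTable, build_design_matrix
from microstm.stm_core import StmConfig, StmFit, fit_stm
from microstm.synthetic import generate_stm_dataset


def make_binary_dataset(M, V, K, effect, seed, library_sizes=None):
    """Synthetic dataset with a binary covariate and a planted effect on the
    first topic's natural parameter."""
    rng = np.random.default_rng(seed)
    meta = pd.DataFrame({"dx": rng.integers(0, 2, size=M)},
                        index=pd.Index([f"S{i:04d}" for i in range(M)]))
    X = build_design_matrix(meta, [("dx", "identity")])
    gamma = np.zeros((2, K - 1))
    gamma[1, 0] = effect
    ds = generate_stm_dataset(M, V, K, X=X, gamma=gamma, seed=seed + 7919,
                              library_sizes=library_sizes)
    return ds, X


def match_topics(beta_fit, beta_true):
    """Hungarian assignment of fitted to true topics by total-variation
    distance; returns (true->fitted map, matched TV distances)."""
    K = beta_fit.shape[0]
    D = np.array([[0.5 * np.abs(beta_fit[i] - beta_true[j]).sum() for j in range(K)]
                  for i in range(K)])
    r, c = linear_sum_assignment(D)
    return {int(j): int(i) for i, j in zip(r, c)}, D[r, c]


@pytest.fixture(scope="session")
def planted_dataset():
    """One moderate-size dataset with a planted covariate effect, plus fit."""
    ds, X = make_binary_dataset(150, 80, 3, effect=1.0, seed=0)
    fit = fit_stm(ds.table, X, StmConfig(K=3, seed=0))
    return ds, X, fit


@pytest.fixture()
def tiny_fit():
    """Hand-built 2-topic, 3-OTU, 2-sample fit with degenerate (zero)
    posterior covariance, so theta is deterministic."""
    beta = np.array([[0.6, 0.3, 0.1],
                     [0.1, 0.2, 0.7]])
    eta = np.array([[0.8], [-0.5]])
    theta = np.column_stack([np.exp(eta[:, 0]), np.ones(2)])
    theta /= theta.sum(axis=1, keepdims=True)
    return StmFit(
        theta=theta, beta=beta, gamma=np.zeros((1, 1)), sigma=np.eye(1),
        eta_mean=eta, eta_cov=np.zeros((2, 1, 1)), elbo_trace=[0.0],
        config=StmConfig(K=2), vocabulary=["A", "B", "C"],
        sample_ids=["s1", "s2"])


@pytest.fixture()
def small_table():
    counts = np.array([[10.0, 0.0, 5.0],
                       [2.0, 8.0, 0.0]])
    taxonomy = {
        "O1": ("Bacteria", "Firmicutes", "c", "o", "f", "g", "s"),
        "O2": ("Bacteria", "Bacteroidetes", "c", "o", "f", "g", "s"),
        "O3": ("Bacteria", "unknown", "unknown", "unknown", "unknown", "unknown", "unknown"),
    }
    meta = pd.DataFrame({"dx": [1, 0], "day": [3, 9]}, index=pd.Index(["s1", "s2"]))
    return OtuTable(counts, ["s1", "s2"], ["O1", "O2", "O3"], taxonomy, meta)
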