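"""Shared fixtures: small synthetic experiments generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rmicell import simdata
from rmicell.preprocess import compute_size_factors


@pytest.fixture(scope="session")
def default_experiment():
    """Default four-condition experiment at desk scale (600 genes,
    60 cells per condition)."""
    cfg = simdata.default_config(seed=11, n_genes=600, n_cells_per_condition=60)
    em, truth = simdata.simulate_experiment(cfg)
    return em, truth


@pytest.fixture(scope="session")
def default_normalized(default_experiment):
    em, truth = default_experiment
    return compute_size_factors(em), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def gaussian_sample(n: int, d: int, rho: float, seed: int) -> np.ndarray:
    """Equicorrelated multivariate normal sample (helper, not a fixture)."""
    R = np.full((d, d), rho)
    np.fill_diagonal(R, 1.0)
    L = np.linalg.cholesky(R)
    return np.random.default_rng(seed).standard_normal((n, d)) @ L.T
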