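import logging

import numpy as np
import pandas as pd
import pytest

from coexphys.preprocess import normalize
from coexphys.simulate import SimulationConfig, simulate_dataset

logging.disable(logging.WARNING)

BALANCED_DESIGN = (
    ("N.Ref", 12, 10), ("TE", 12, 10), ("S.Ref", 12, 10),
    ("N.Ref", 28, 10), ("TE", 28, 10), ("S.Ref", 28, 10),
)


@pytest.fixture(scope="session")
def planted_dataset():
    """600 genes, 3 planted modules of 50, 60 balanced samples."""
    cfg = SimulationConfig(
        n_genes=600, module_sizes=(50, 50, 50), design=BALANCED_DESIGN,
        loading_range=(0.8, 1.2), dispersion=0.2,
        de_acclim_fraction=0.0, de_pop_fraction=0.0, seed=7)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def planted_log_expr(planted_dataset):
    return normalize(planted_dataset.counts).log_values


def exact_correlation_data(rng, target_cor, n_samples):
    """Gaussian samples whose empirical correlation matrix equals target."""
    target = np.asarray(target_cor, dtype=float)
    p = target.shape[0]
    if n_samples <= p:
        raise ValueError("need n_samples > n_genes for an exact construction")
    x = rng.standard_normal((n_samples, p))
    x -= x.mean(axis=0)
    # whiten the empirical covariance, then color with the target
    cov = x.T @ x / (n_samples - 1)
    chol = np.linalg.cholesky(cov)
    whitened = x @ np.linalg.inv(chol).T
    colored = whitened @ np.linalg.cholesky(target).T
    return pd.DataFrame(colored.T,
                        index=[f"g{i}" for i in range(p)],
                        columns=[f"s{j}" for j in range(n_samples)])
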