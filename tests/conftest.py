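import numpy as np
import pandas as pd
import pytest

from degsig.simcohort import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-parameter cohort (5000 genes, 30 samples), shared."""
    return simulate_cohort(SimConfig(seed=0))


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale config used by stochastic multi-seed tests."""
    return SimConfig(
        n_genes=1500,
        n_up_total=200,
        n_down_total=300,
        n_signature=100,
        seed=0,
    )


def null_config(n_genes: int = 2000, seed: int = 0) -> SimConfig:
    """No planted effects anywhere: DE, coupling and decoupling all off."""
    cfg = SimConfig(
        n_genes=n_genes,
        n_up_total=0,
        n_down_total=0,
        n_signature=0,
        seed=seed,
    )
    return cfg.with_(
        beta_range=(0.0, 0.0),
        behavior_params=cfg.behavior_params.__class__(decouple=False),
    )


def small_sim(n_genes: int, seed: int = 0, **kwargs) -> SimConfig:
    """Default-shaped config with planted-set sizes scaled to n_genes."""
    base = dict(
        n_genes=n_genes,
        n_up_total=max(int(0.10 * n_genes), 1),
        n_down_total=max(int(0.15 * n_genes), 1),
        n_signature=int(0.05 * n_genes),
        seed=seed,
    )
    base.update(kwargs)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def nb_matrix(rng, n_genes, n_samples, mean_range=(20, 500), phi=0.1):
    """Plain NB count matrix with equal expected library sizes."""
    mu = rng.uniform(*mean_range, size=n_genes)[:, None] * np.ones((1, n_samples))
    if phi == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / phi
        counts = rng.negative_binomial(r, r / (r + mu))
    return counts.astype(np.int64)
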