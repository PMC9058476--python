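import numpy as np
import pytest

from confluentq import (SynthConfig, correlation_matrix, generate_nac_dataset,
                        standardized_matrix)


@pytest.fixture(scope="session")
def small_dataset():
    """~3000-atom, 20-method synthetic table with ground truth."""
    config = SynthConfig(n_molecules=200, seed=11)
    return generate_nac_dataset(config)


@pytest.fixture(scope="session")
def medium_dataset():
    """~15000-atom table; correlations close to their closed forms."""
    config = SynthConfig(n_molecules=1000, seed=7)
    return generate_nac_dataset(config)


@pytest.fixture(scope="session")
def medium_summary(medium_dataset):
    table, _ = medium_dataset
    return correlation_matrix(table)


@pytest.fixture(scope="session")
def medium_w(medium_dataset):
    table, _ = medium_dataset
    return standardized_matrix(table)


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)


def random_correlated_pair(rng, n=200, rho=None):
    """Two positively correlated columns with random scales and offsets."""
    if rho is None:
        rho = rng.uniform(0.3, 0.99)
    base = rng.standard_normal(n)
    noise = rng.standard_normal(n)
    x = base
    y = rho * base + np.sqrt(1 - rho ** 2) * noise
    sx, sy = rng.uniform(0.2, 5.0, 2)
    return sx * x + rng.normal(0, 2), sy * y + rng.normal(0, 2)
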