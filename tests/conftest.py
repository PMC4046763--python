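import numpy as np
import pandas as pd
import pytest

from gradprog.config import SyntheticConfig
from gradprog.synthetic import simulate_study


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A scaled-down study used by most integration tests."""
    return SyntheticConfig(
        n_genes=600, n_mirnas=40, n_sets=15, n_enriched_sets=4,
        set_size_range=(8, 15), seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def two_group_matrix(rng, n_genes=50, na=5, nb=5, sd=0.5, shift=None):
    """Plain two-group matrix helper; shift is {row: delta} on group a."""
    cols = [f"a{i}" for i in range(na)] + [f"b{i}" for i in range(nb)]
    x = rng.normal(8.0, 1.0, (n_genes, 1)) + rng.normal(0, sd, (n_genes, na + nb))
    if shift:
        for row, delta in shift.items():
            x[row, :na] += delta
    return (
        pd.DataFrame(x, index=[f"g{i}" for i in range(n_genes)], columns=cols),
        cols[:na],
        cols[na:],
    )
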