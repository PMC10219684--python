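import numpy as np
import pandas as pd
import pytest

from cardiomat.simulate import SimulationConfig, simulate_count_compendium, simulate_regulons


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(seed=11, n_genes=1500, n_tfs=40, planted_tfs=4)


@pytest.fixture(scope="session")
def small_compendium(small_config):
    edges, _ = simulate_regulons(small_config)
    counts, design, truth = simulate_count_compendium(small_config, edges)
    return edges, counts, design, truth


def nb_counts(rng, mu, alpha, shape):
    """Negative-binomial draws with var = mu + alpha*mu^2."""
    if alpha <= 0:
        return rng.poisson(mu, shape)
    n = 1.0 / alpha
    return rng.negative_binomial(n, n / (n + mu), shape)


@pytest.fixture()
def null_counts():
    """2 conditions x 3 replicates of NB noise with no true differences."""

    def make(n_genes=2000, alpha=0.1, seed=0):
        rng = np.random.default_rng(seed)
        mu = 2.0 ** rng.normal(7, 1.5, n_genes)
        counts = pd.DataFrame(
            nb_counts(rng, mu[:, None], alpha, (n_genes, 6)),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{j}" for j in range(6)],
        )
        design = pd.DataFrame(
            {"condition": ["a"] * 3 + ["b"] * 3, "dataset": "d", "replicate": [1, 2, 3] * 2},
            index=counts.columns,
        )
        return counts, design

    return make
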