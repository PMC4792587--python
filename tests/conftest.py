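import numpy as np
import pytest

from prsog import RankVector, SimulationConfig, simulate_experiment

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def small_config():
    """A fast two-study experiment: 300 genes, planted 30-gene overlap on hubs."""
    return SimulationConfig(
        n_genes=300, n_samples_1=40, n_samples_2=40, n_modules=5,
        within_module_corr=0.7, deg_len_1=90, deg_len_2=80, overlap_k=30,
        overlap_placement="high_rank", missing_rate=0.0, seed=11,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return simulate_experiment(small_config)


@pytest.fixture()
def heavy_tail_ranks():
    """A tie-free heavy-tailed rank vector over 500 genes, summing to 1."""
    rng = np.random.default_rng(505)
    values = rng.pareto(1.5, 500) + 1.0
    values /= values.sum()
    return RankVector([f"g{i:03d}" for i in range(500)], values,
                      iterations_used=0, converged=True)


def make_rank_vector(values):
    values = np.asarray(values, dtype=float)
    values = values / values.sum()
    return RankVector([f"g{i:03d}" for i in range(values.size)], values,
                      iterations_used=0, converged=True)
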