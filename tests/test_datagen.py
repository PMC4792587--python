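"""Generator contracts: exact overlap, determinism, correlation and missingness."""

import numpy as np
import pytest

from prsog import (
    ConfigurationError,
    SimulationConfig,
    read_deg_list,
    read_expression,
    simulate_experiment,
    write_experiment,
)


def test_overlap_count_is_exact(small_experiment, small_config):
    shared = small_experiment.degs_1.as_set() & small_experiment.degs_2.as_set()
    assert len(shared) == small_config.overlap_k
    assert shared == small_experiment.truth.overlap
    assert len(small_experiment.degs_1) == small_config.deg_len_1
    assert len(small_experiment.degs_2) == small_config.deg_len_2


def test_breast_cancer_sized_lists_share_308_genes():
    """DEG lists of 963/856 with the overlap that rounds to POG 0.32/0.36."""
    cfg = SimulationConfig(n_genes=2000, deg_len_1=963, deg_len_2=856,
                           overlap_k=308, missing_rate=0.0, seed=1,
                           n_samples_1=6, n_samples_2=6)
    exp = simulate_experiment(cfg)
    k = len(exp.degs_1.as_set() & exp.degs_2.as_set())
    assert (len(exp.degs_1), len(exp.degs_2), k) == (963, 856, 308)
    assert round(k / 963, 2) == 0.32
    assert round(k / 856, 2) == 0.36


def test_zero_overlap_gives_disjoint_lists():
    cfg = SimulationConfig(n_genes=120, deg_len_1=20, deg_len_2=25, overlap_k=0,
                           n_samples_1=8, n_samples_2=8, missing_rate=0.0, seed=3)
    exp = simulate_experiment(cfg)
    assert not (exp.degs_1.as_set() & exp.degs_2.as_set())


def test_same_seed_bit_identical():
    cfg = SimulationConfig(n_genes=80, deg_len_1=15, deg_len_2=15, overlap_k=5,
                           n_samples_1=10, n_samples_2=12, missing_rate=0.05, seed=9)
    a, b = simulate_experiment(cfg), simulate_experiment(cfg)
    assert a.degs_1.gene_ids == b.degs_1.gene_ids
    assert a.degs_2.gene_ids == b.degs_2.gene_ids
    np.testing.assert_array_equal(a.expr_1.values, b.expr_1.values)
    np.testing.assert_array_equal(a.expr_2.values, b.expr_2.values)


def test_shared_gene_universe_and_order(small_experiment):
    assert small_experiment.expr_1.gene_ids == small_experiment.expr_2.gene_ids


@pytest.mark.parametrize("bad", [
    dict(overlap_k=50, deg_len_1=40, deg_len_2=60),
    dict(n_genes=50, deg_len_1=40, deg_len_2=40, overlap_k=10),
    dict(within_module_corr=1.5),
    dict(missing_rate=1.0),
    dict(overlap_placement="hubs"),
])
def test_invalid_configs_rejected(bad):
    cfg = SimulationConfig(**{**dict(n_genes=100, deg_len_1=20, deg_len_2=20,
                                     overlap_k=5, seed=0), **bad})
    with pytest.raises(ConfigurationError):
        cfg.validate()


def test_within_module_correlation_converges():
    """Empirical within-module correlation approaches the target at n=500."""
    cfg = SimulationConfig(n_genes=60, n_samples_1=500, n_samples_2=4,
                           n_modules=3, within_module_corr=0.6,
                           deg_len_1=5, deg_len_2=5, overlap_k=5,
                           overlap_placement="low_rank", effect_size=0.0,
                           missing_rate=0.0, seed=21)
    exp = simulate_experiment(cfg)
    module_of = exp.truth.module_of
    X = exp.expr_1.values
    idx = {g: i for i, g in enumerate(exp.expr_1.gene_ids)}
    offdiag = []
    for m in range(cfg.n_modules):
        rows = [idx[g] for g, mm in module_of.items() if mm == m]
        C = np.corrcoef(X[rows])
        offdiag.append(C[np.triu_indices(len(rows), 1)])
    mean_corr = np.concatenate(offdiag).mean()
    assert abs(mean_corr - 0.6) < 0.05


def test_missing_rate_matches_request():
    cfg = SimulationConfig(n_genes=200, n_samples_1=60, n_samples_2=60,
                           deg_len_1=10, deg_len_2=10, overlap_k=5,
                           missing_rate=0.1, seed=13)
    exp = simulate_experiment(cfg)
    frac = np.isnan(np.hstack([exp.expr_1.values, exp.expr_2.values])).mean()
    assert abs(frac - 0.1) < 0.01


def test_high_rank_overlap_sits_in_largest_modules():
    cfg = SimulationConfig(n_genes=300, deg_len_1=60, deg_len_2=60, overlap_k=20,
                           n_samples_1=10, n_samples_2=10, n_modules=5,
                           overlap_placement="high_rank", missing_rate=0.0, seed=7)
    exp = simulate_experiment(cfg)
    sizes = {}
    for g, m in exp.truth.module_of.items():
        sizes[m] = sizes.get(m, 0) + 1
    largest = max((m for m in sizes if m >= 0), key=lambda m: sizes[m])
    in_largest = sum(exp.truth.module_of[g] == largest for g in exp.truth.overlap)
    assert in_largest == len(exp.truth.overlap)


def test_low_rank_overlap_sits_on_singletons():
    cfg = SimulationConfig(n_genes=300, deg_len_1=60, deg_len_2=60, overlap_k=20,
                           n_samples_1=10, n_samples_2=10, n_modules=5,
                           module_gene_frac=0.6,
                           overlap_placement="low_rank", missing_rate=0.0, seed=7)
    exp = simulate_experiment(cfg)
    assert all(exp.truth.module_of[g] == -1 for g in exp.truth.overlap)


def test_written_experiment_round_trips(tmp_path):
    cfg = SimulationConfig(n_genes=40, deg_len_1=8, deg_len_2=8, overlap_k=3,
                           n_samples_1=6, n_samples_2=6, missing_rate=0.05, seed=2)
    exp = simulate_experiment(cfg)
    paths = write_experiment(exp, tmp_path)
    expr = read_expression(paths["expr_1"])
    np.testing.assert_allclose(expr.values, exp.expr_1.values, rtol=0, atol=1e-12)
    assert expr.gene_ids == exp.expr_1.gene_ids
    degs = read_deg_list(paths["degs_1"])
    assert degs.gene_ids == exp.degs_1.gene_ids
    manifest = paths["manifest"].read_text()
    assert f"overlap_k = {cfg.overlap_k}" in manifest
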