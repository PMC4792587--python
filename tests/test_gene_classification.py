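"""Bootstrap importance p-values, the three-class scheme, heavy-tail fits."""

import numpy as np
import pandas as pd
import pytest

from prsog import (
    FitError,
    class_composition,
    classify,
    fit_distribution,
    gene_pvalues,
)

from conftest import make_rank_vector


# ---------------------------------------------------------------------------
# Bootstrap p-values
# ---------------------------------------------------------------------------

def test_unique_maximum_has_zero_pvalue():
    rv = make_rank_vector([10.0, 2.0, 1.0, 1.0, 0.5])
    table = gene_pvalues(rv, replicates=200, seed=1)
    assert table.loc["g000", "p_value"] == 0.0
    assert table.loc["g000", "p_sd"] == 0.0


def test_unique_minimum_approaches_one():
    rng = np.random.default_rng(2)
    vals = np.sort(rng.random(100))[::-1] + 1.0
    rv = make_rank_vector(vals)
    table = gene_pvalues(rv, replicates=2000, seed=3)
    worst = table["p_value"].max()
    assert worst == pytest.approx(0.99, abs=0.01)


def test_mean_pvalue_matches_plugin_expectation():
    """Bootstrap mean converges to #(rank > rank_i)/N (within 3 SE at 1e4 reps)."""
    rng = np.random.default_rng(4)
    vals = rng.random(10) + 0.5
    rv = make_rank_vector(vals)
    reps = 10_000
    table = gene_pvalues(rv, replicates=reps, seed=5)
    for gene, row in table.iterrows():
        plug = (rv.rank > rv.rank[rv.gene_ids.index(gene)]).sum() / rv.n
        se = max(row["p_sd"] / np.sqrt(reps), 1e-12)
        assert abs(row["p_value"] - plug) <= max(3 * se, 5e-4)


def test_tied_ranks_share_pvalues():
    rv = make_rank_vector([4.0, 2.0, 2.0, 1.0])
    table = gene_pvalues(rv, replicates=500, seed=6)
    assert table.loc["g001", "p_value"] == table.loc["g002", "p_value"]


def test_deterministic_under_seed(heavy_tail_ranks):
    a = gene_pvalues(heavy_tail_ranks, replicates=300, seed=9)
    b = gene_pvalues(heavy_tail_ranks, replicates=300, seed=9)
    pd.testing.assert_frame_equal(a, b)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def test_threshold_application():
    table = pd.DataFrame({"p_value": [0.05, 0.1, 0.5, 0.9, 0.95],
                          "p_sd": [0.0] * 5},
                         index=pd.Index(list("abcde"), name="gene_id"))
    out = classify(table, overlap={"a", "c"})
    assert list(out["class"]) == ["significant", "significant", "common",
                                  "wrong", "wrong"]
    assert list(out["in_overlap"]) == [True, False, True, False, False]


def test_classes_partition_the_pool(heavy_tail_ranks):
    table = classify(gene_pvalues(heavy_tail_ranks, replicates=1000, seed=10))
    assert table["class"].isin(["significant", "common", "wrong"]).all()
    assert len(table) == heavy_tail_ranks.n


def test_tie_free_pool_is_about_eighty_percent_common(heavy_tail_ranks):
    """With continuous ranks the (0.1, 0.9] band holds ~80% of the pool."""
    table = classify(gene_pvalues(heavy_tail_ranks, replicates=10_000, seed=11))
    comp = class_composition(table)
    assert comp["common"] == pytest.approx(0.80, abs=0.03)
    assert comp["significant"] == pytest.approx(0.10, abs=0.03)
    assert comp["wrong"] == pytest.approx(0.10, abs=0.03)


def test_random_overlap_composition_mirrors_pool(heavy_tail_ranks):
    rng = np.random.default_rng(12)
    overlap = set(rng.choice(heavy_tail_ranks.gene_ids, size=200, replace=False))
    table = classify(gene_pvalues(heavy_tail_ranks, replicates=2000, seed=13),
                     overlap=overlap)
    pool_comp = class_composition(table)
    over_comp = class_composition(table, overlap_only=True)
    assert over_comp["common"] == pytest.approx(pool_comp["common"], abs=0.08)


# ---------------------------------------------------------------------------
# Distribution fitting
# ---------------------------------------------------------------------------

def sample_power_law(n, alpha, xmin, rng):
    return xmin * (1.0 - rng.random(n)) ** (-1.0 / (alpha - 1.0))


def test_power_law_exponent_recovered():
    """alpha = 2.5 recovered within +-0.1 from 5000 draws; the fit is accepted."""
    rng = np.random.default_rng(14)
    data = sample_power_law(5000, 2.5, 1e-3, rng)
    fit = fit_distribution(data, "power_law", n_bootstrap=100, seed=15)
    assert fit.params["alpha"] == pytest.approx(2.5, abs=0.1)
    assert fit.ks_p > 0.05
    assert fit.x_min > 0 and fit.n_tail >= 10


def test_exponential_goodness_of_fit_calibrated():
    """Exponential data fitted as exponential: K-S p > 0.05 in >= 90% of runs."""
    rng = np.random.default_rng(16)
    accept = 0
    runs = 10
    for _ in range(runs):
        data = 1e-3 + rng.exponential(2e-3, size=800)
        fit = fit_distribution(data, "exponential", n_bootstrap=60,
                               seed=int(rng.integers(2**31)))
        accept += fit.ks_p > 0.05
    assert accept >= 0.9 * runs


def test_true_family_beats_misspecified_alternative():
    """The generating family has smaller K-S distance than a clearly wrong one.

    Power-law vs exponential in both directions.  Truncated log-normal is not
    used as the foil: with a free tail cutoff it can mimic either family, a
    well-known limit of K-S-based model selection on heavy tails.
    """
    rng = np.random.default_rng(17)
    wins_pl = wins_exp = 0
    runs = 10
    for _ in range(runs):
        pl = sample_power_law(1000, 2.5, 1e-3, rng)
        wins_pl += (fit_distribution(pl, "power_law", n_bootstrap=0).ks_stat
                    < fit_distribution(pl, "exponential", n_bootstrap=0).ks_stat)
        ex = 1e-3 + rng.exponential(2e-3, size=1000)
        wins_exp += (fit_distribution(ex, "exponential", n_bootstrap=0).ks_stat
                     < fit_distribution(ex, "power_law", n_bootstrap=0).ks_stat)
    assert wins_pl >= 0.8 * runs
    assert wins_exp >= 0.8 * runs


def test_fixed_xmin_is_honoured():
    rng = np.random.default_rng(18)
    data = sample_power_law(2000, 2.2, 5e-4, rng)
    fit = fit_distribution(data, "power_law", x_min=1e-3, n_bootstrap=0)
    assert fit.x_min == 1e-3
    assert fit.params["alpha"] == pytest.approx(2.2, abs=0.15)


def test_non_positive_ranks_refuse_fit():
    data = np.concatenate([np.full(50, 0.01), [0.0]])
    with pytest.raises(FitError, match="non-positive"):
        fit_distribution(data, "power_law")


def test_tiny_tail_refused():
    with pytest.raises(FitError):
        fit_distribution(np.full(5, 0.1), "power_law")
    rng = np.random.default_rng(19)
    data = sample_power_law(30, 2.5, 1e-3, rng)
    with pytest.raises(FitError, match="tail"):
        fit_distribution(data, "power_law", x_min=float(np.sort(data)[-5]))
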