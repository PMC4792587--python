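"""Per-gene importance p-values, the three-class scheme, and rank-distribution fits.

Bootstrap importance p-value
----------------------------
For gene i the importance p-value is the probability that a randomly chosen
gene outranks it: p_i = #(rank(g) > rank(g_i)) / N, evaluated in rank vectors
R' resampled from R with replacement.  The reported p-value is the mean over
replicates (its SD is reported alongside); by the law of large numbers it
converges to the plug-in fraction of genes strictly above gene i.  Ties share
the same strict-exceedance count, so equally ranked genes get equal p-values.

Classification
--------------
Genes are classified by the bootstrap p-value: *significant* (p <= 0.1, few
genes outrank them — the network's important genes), *wrong* (p >= 0.9,
almost everything outranks them), *common* (in between).  With tie-free
ranks this partitions the pool into roughly 10% / 80% / 10%.  The class
composition of the overlap set diagnoses *why* an experiment's PRSOG is
significant or not: overlaps rich in significant genes and free of wrong
genes reproduce well.

Distribution fitting
--------------------
PageRank vectors on co-expression networks are heavy-tailed; power-law,
exponential, and (truncated) log-normal models are fitted to the tail of the
rank values above a cutoff x_min chosen by Kolmogorov–Smirnov distance
minimization (the Clauset–Shalizi–Newman recipe), with parameters by maximum
likelihood and a parametric-bootstrap K-S p-value.  Fitting is refused when
any rank is non-positive (isolated genes under near-zero rank handling) or
when fewer than 10 tail points remain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import FitError
from .pagerank import RankVector

FAMILIES = ("power_law", "exponential", "log_normal")
CLASSES = ("significant", "common", "wrong")


# ---------------------------------------------------------------------------
# Bootstrap p-values and classification
# ---------------------------------------------------------------------------

def gene_pvalues(
    ranks: RankVector,
    replicates: int = 10000,
    seed: int | None = None,
    chunk: int = 2000,
) -> pd.DataFrame:
    """Bootstrap mean and SD of the per-gene importance p-value.

    Each replicate resamples N ranks with replacement and computes, for every
    gene, the fraction of resampled values strictly exceeding its rank.
    Returns a DataFrame indexed by gene_id with columns p_value (mean over
    replicates) and p_sd.
    """
    if ranks.n < 2:
        raise ValueError("need at least 2 genes")
    rank = np.asarray(ranks.rank, dtype=float)
    n = rank.size
    order = np.argsort(-rank, kind="stable")        # descending
    sorted_r = rank[order]
    # number of genes strictly above each sorted position (ties collapse)
    greater = np.searchsorted(-sorted_r, -sorted_r, side="left")

    rng = np.random.default_rng(seed)
    sum_p = np.zeros(n)
    sum_p2 = np.zeros(n)
    done = 0
    while done < replicates:
        m = min(chunk, replicates - done)
        # multinomial counts of each original gene in the resampled vector,
        # columns arranged in descending-rank order
        counts = rng.multinomial(n, np.full(n, 1.0 / n), size=m)[:, order]
        cum = np.cumsum(counts, axis=1)
        # exceedance count for sorted position j = resampled mass on the
        # `greater[j]` genes strictly above it
        cum_pad = np.hstack([np.zeros((m, 1), dtype=cum.dtype), cum])
        p = cum_pad[:, greater] / n
        sum_p += p.sum(axis=0)
        sum_p2 += (p ** 2).sum(axis=0)
        done += m

    mean_sorted = sum_p / replicates
    var_sorted = np.maximum(sum_p2 / replicates - mean_sorted ** 2, 0.0)
    sd_sorted = np.sqrt(var_sorted * replicates / max(replicates - 1, 1))
    p_value = np.empty(n)
    p_sd = np.empty(n)
    p_value[order] = mean_sorted
    p_sd[order] = sd_sorted
    return pd.DataFrame(
        {"p_value": p_value, "p_sd": p_sd},
        index=pd.Index(ranks.gene_ids, name="gene_id"),
    )


def classify(
    table: pd.DataFrame,
    overlap: set[str] | None = None,
    significant_max: float = 0.1,
    wrong_min: float = 0.9,
) -> pd.DataFrame:
    """Attach class labels and overlap flags to a gene p-value table.

    significant: p <= significant_max; wrong: p >= wrong_min; common otherwise.
    """
    if not 0 < significant_max < wrong_min < 1:
        raise ValueError("need 0 < significant_max < wrong_min < 1")
    out = table.copy()
    p = out["p_value"].to_numpy()
    cls = np.where(p <= significant_max, "significant",
                   np.where(p >= wrong_min, "wrong", "common"))
    out["class"] = cls
    out["in_overlap"] = (
        out.index.isin(set(overlap)) if overlap is not None else False
    )
    return out


def class_composition(table: pd.DataFrame, overlap_only: bool = False) -> pd.Series:
    """Fractions of significant/common/wrong genes (pool or overlap subset)."""
    sub = table[table["in_overlap"]] if overlap_only else table
    if len(sub) == 0:
        return pd.Series(0.0, index=list(CLASSES))
    frac = sub["class"].value_counts(normalize=True)
    return frac.reindex(CLASSES, fill_value=0.0)


# ---------------------------------------------------------------------------
# Heavy-tail distribution fitting
# ---------------------------------------------------------------------------

@dataclass
class DistributionFit:
    family: str
    x_min: float
    params: dict[str, float]
    ks_stat: float
    ks_p: float | None
    n_tail: int


MIN_TAIL = 10


def fit_distribution(
    ranks: RankVector | np.ndarray,
    family: str,
    x_min: float | None = None,
    n_bootstrap: int = 100,
    max_xmin_candidates: int = 100,
    seed: int | None = None,
) -> DistributionFit:
    """Fit a heavy-tail family to the rank values above an estimated x_min.

    x_min (unless given) minimizes the K-S distance between the empirical
    tail and the family fitted to that tail by maximum likelihood.  The K-S
    p-value comes from ``n_bootstrap`` parametric-bootstrap resamples of the
    fitted tail model (parameters refitted per resample, x_min held fixed);
    pass ``n_bootstrap=0`` to skip it.
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}, got {family!r}")
    data = np.asarray(ranks.rank if isinstance(ranks, RankVector) else ranks,
                      dtype=float)
    if data.size < MIN_TAIL:
        raise FitError(f"need at least {MIN_TAIL} values, got {data.size}")
    if (data <= 0).any():
        raise FitError(
            "non-positive rank values present (isolated genes?); "
            "heavy-tail fitting is undefined — fit refused"
        )
    data = np.sort(data)

    if x_min is not None:
        candidates = [float(x_min)]
    else:
        uniq = np.unique(data)
        uniq = uniq[uniq <= data[-MIN_TAIL]]       # keep >= MIN_TAIL tail points
        if uniq.size == 0:
            raise FitError(f"fewer than {MIN_TAIL} tail points beyond any x_min")
        if uniq.size > max_xmin_candidates:
            take = np.unique(np.linspace(0, uniq.size - 1,
                                         max_xmin_candidates).astype(int))
            uniq = uniq[take]
        candidates = [float(u) for u in uniq]

    best: tuple[float, float, dict[str, float], int] | None = None
    for xm in candidates:
        tail = data[data >= xm]
        if tail.size < MIN_TAIL:
            raise FitError(
                f"fewer than {MIN_TAIL} tail points beyond x_min={xm:.4g} "
                f"({tail.size} found)"
            )
        try:
            params = _mle(family, tail, xm)
        except FitError:
            continue
        ks = _ks_distance(family, tail, xm, params)
        if not np.isfinite(ks):
            continue
        if best is None or ks < best[1]:
            best = (xm, ks, params, tail.size)
    if best is None:
        raise FitError(f"maximum-likelihood fit failed for every candidate x_min "
                       f"({family})")
    xm, ks, params, n_tail = best

    ks_p: float | None = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_bootstrap):
            sim = _sample(family, n_tail, xm, params, rng)
            try:
                p_sim = _mle(family, sim, xm)
            except FitError:
                exceed += 1
                continue
            if _ks_distance(family, np.sort(sim), xm, p_sim) >= ks:
                exceed += 1
        ks_p = (exceed + 1) / (n_bootstrap + 1)

    return DistributionFit(family=family, x_min=xm, params=params,
                           ks_stat=ks, ks_p=ks_p, n_tail=n_tail)


def _mle(family: str, tail: np.ndarray, xm: float) -> dict[str, float]:
    n = tail.size
    if family == "power_law":
        logs = np.log(tail / xm)
        s = logs.sum()
        if s <= 0:
            raise FitError("degenerate tail (all values at x_min)")
        return {"alpha": 1.0 + n / s}
    if family == "exponential":
        m = float((tail - xm).mean())
        if m <= 0:
            raise FitError("degenerate tail (all values at x_min)")
        return {"lam": 1.0 / m}
    # truncated log-normal on [x_min, inf)
    logs = np.log(tail)
    mu0, sd0 = float(logs.mean()), float(logs.std(ddof=0))
    sd0 = max(sd0, 1e-6)

    def nll(theta):
        mu, log_sd = theta
        sd = math.exp(log_sd)
        ll = stats.norm.logpdf(logs, loc=mu, scale=sd) - logs
        log_tail_mass = stats.norm.logsf(math.log(xm), loc=mu, scale=sd)
        return -(ll.sum() - n * log_tail_mass)

    res = optimize.minimize(nll, x0=[mu0, math.log(sd0)], method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    if not np.isfinite(res.fun):
        raise FitError("truncated log-normal likelihood did not converge")
    mu, log_sd = res.x
    return {"mu": float(mu), "sigma": float(math.exp(log_sd))}


def _cdf(family: str, x: np.ndarray, xm: float, params: dict[str, float]) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if family == "power_law":
        return 1.0 - (x / xm) ** (1.0 - params["alpha"])
    if family == "exponential":
        return 1.0 - np.exp(-params["lam"] * (x - xm))
    mu, sd = params["mu"], params["sigma"]
    # stable survival-function route: 1 - S(x)/S(x_min) in log space
    log_sf_x = stats.norm.logsf(np.log(x), loc=mu, scale=sd)
    log_sf_xm = stats.norm.logsf(math.log(xm), loc=mu, scale=sd)
    return 1.0 - np.exp(log_sf_x - log_sf_xm)


def _ks_distance(family: str, tail_sorted: np.ndarray, xm: float,
                 params: dict[str, float]) -> float:
    n = tail_sorted.size
    cdf = _cdf(family, tail_sorted, xm, params)
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    return float(np.max(np.maximum(np.abs(ecdf_hi - cdf), np.abs(cdf - ecdf_lo))))


def _sample(family: str, n: int, xm: float, params: dict[str, float],
            rng: np.random.Generator) -> np.ndarray:
    u = rng.random(n)
    if family == "power_law":
        return xm * (1.0 - u) ** (-1.0 / (params["alpha"] - 1.0))
    if family == "exponential":
        return xm + rng.exponential(1.0 / params["lam"], size=n)
    mu, sd = params["mu"], params["sigma"]
    # inverse-survival sampling of the tail: S(x) = S(x_min) * (1 - u)
    s_xm = math.exp(stats.norm.logsf(math.log(xm), loc=mu, scale=sd))
    return np.exp(stats.norm.isf(s_xm * (1.0 - u), loc=mu, scale=sd))
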