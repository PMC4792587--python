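"""Gene pool construction and thresholded correlation networks.

The node set ("gene pool") is the union of the two studies' DEG lists,
restricted to genes actually measured in both expression matrices.  Edges
connect gene pairs whose expression correlation clears a threshold r; the
graph is simple and undirected, and isolated genes stay in the pool.

Which samples feed the correlation is configurable (``correlation_source``):
the default ``"pooled"`` concatenates both studies' samples, which is
symmetric in the two studies and uses all information; ``"study1"`` /
``"study2"`` restrict to one cohort.  By co-expression convention the default
edge rule is |rho| >= r (anti-correlated partners count); signed thresholding
is available via ``use_absolute=False``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np
from scipy import stats

from .exceptions import PipelineError
from .io_preprocess import DegList, ExpressionMatrix

logger = logging.getLogger(__name__)

CORRELATION_SOURCES = ("pooled", "study1", "study2")


@dataclass
class GenePool:
    """Ordered union of two DEG lists over the measured gene universe."""

    gene_ids: list[str]

    @property
    def n(self) -> int:
        return len(self.gene_ids)

    def index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.gene_ids)

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class GeneNetwork:
    """Thresholded correlation graph over a gene pool (isolated genes kept)."""

    pool: GenePool
    graph: nx.Graph
    r_threshold: float
    correlation_source: str
    use_absolute: bool

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, gene: str) -> int:
        return int(self.graph.degree[gene])

    def degrees(self) -> np.ndarray:
        return np.array([self.graph.degree[g] for g in self.pool.gene_ids], dtype=int)

    def edges(self) -> set[frozenset]:
        return {frozenset((a, b)) for a, b in self.graph.edges()}


def build_pool(
    degs_1: DegList, degs_2: DegList, measured: Iterable[str]
) -> GenePool:
    """Union of the two DEG lists, list-1 order first, then novel list-2 genes.

    Genes absent from the measured universe are dropped (count logged); an
    empty result raises :class:`PipelineError`.
    """
    measured_set = set(measured)
    seen: set[str] = set()
    pool: list[str] = []
    dropped = 0
    for g in list(degs_1.gene_ids) + list(degs_2.gene_ids):
        if g in seen:
            continue
        seen.add(g)
        if g not in measured_set:
            dropped += 1
            continue
        pool.append(g)
    if dropped:
        logger.info("build_pool: dropped %d DEG(s) absent from the measured universe",
                    dropped)
    if not pool:
        raise PipelineError("gene pool is empty: no DEG is present in the "
                            "measured gene universe")
    return GenePool(pool)


def build_network(
    expr_1: ExpressionMatrix,
    expr_2: ExpressionMatrix,
    pool: GenePool,
    r: float,
    correlation_source: str = "pooled",
    use_absolute: bool = True,
    method: str = "pearson",
) -> GeneNetwork:
    """Build the correlation network at threshold r over the pool genes.

    An edge joins genes a != b iff corr(a, b) >= r (absolute value by
    default; closed bound, so r = 1 admits perfectly correlated pairs).
    Zero-variance genes have undefined correlations: their pairs get no edge
    and a warning names the genes.  Matrices must be complete — impute first.
    """
    if correlation_source not in CORRELATION_SOURCES:
        raise ValueError(
            f"correlation_source must be one of {CORRELATION_SOURCES}, "
            f"got {correlation_source!r}"
        )
    if not 0.0 < r <= 1.0:
        raise ValueError(f"r must lie in (0, 1], got {r}")
    X = _correlation_input(expr_1, expr_2, pool, correlation_source)
    if X.shape[1] < 3:
        raise PipelineError(
            f"correlation source {correlation_source!r} has {X.shape[1]} samples; "
            "at least 3 required"
        )
    if np.isnan(X).any():
        raise PipelineError(
            "expression contains missing values; run knn_impute before "
            "building the network"
        )

    logger.info(
        "build_network: r=%.3g, source=%s, %s thresholding, pool N=%d",
        r, correlation_source, "absolute" if use_absolute else "signed", pool.n,
    )
    if method == "pearson":
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(X)
    elif method == "spearman":
        C = stats.spearmanr(X, axis=1).statistic
        C = np.atleast_2d(C)
    else:
        raise ValueError(f"unknown correlation method: {method!r}")

    sd = X.std(axis=1)
    flat = np.where(sd == 0)[0]
    if flat.size:
        warnings.warn(
            "zero-variance gene(s), correlations undefined, no edges created: "
            f"{[pool.gene_ids[i] for i in flat]}",
            stacklevel=2,
        )
        C[flat, :] = np.nan
        C[:, flat] = np.nan

    strength = np.abs(C) if use_absolute else C
    graph = nx.Graph()
    graph.add_nodes_from(pool.gene_ids)
    iu, ju = np.triu_indices(pool.n, k=1)
    s = strength[iu, ju]
    with np.errstate(invalid="ignore"):
        # closed bound with an fp guard so r = 1 admits perfectly correlated pairs
        hit = s >= r - 1e-12
    hit &= ~np.isnan(s)
    for i, j in zip(iu[hit], ju[hit]):
        graph.add_edge(pool.gene_ids[i], pool.gene_ids[j])
    return GeneNetwork(pool, graph, float(r), correlation_source, use_absolute)


def _correlation_input(
    expr_1: ExpressionMatrix,
    expr_2: ExpressionMatrix,
    pool: GenePool,
    source: str,
) -> np.ndarray:
    parts = []
    for expr, wanted in ((expr_1, source in ("pooled", "study1")),
                         (expr_2, source in ("pooled", "study2"))):
        if not wanted:
            continue
        idx = expr.gene_index()
        missing = [g for g in pool.gene_ids if g not in idx]
        if missing:
            raise PipelineError(
                f"pool gene(s) absent from expression matrix: {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
        rows = np.array([idx[g] for g in pool.gene_ids])
        parts.append(expr.values[rows])
    return np.hstack(parts)


def write_network(network: GeneNetwork, prefix) -> None:
    """Export as <prefix>.edges.tsv (two columns) + <prefix>.nodes.tsv."""
    with open(f"{prefix}.edges.tsv", "wt", encoding="utf-8") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in network.graph.edges()):
            fh.write(f"{a}\t{b}\n")
    with open(f"{prefix}.nodes.tsv", "wt", encoding="utf-8") as fh:
        fh.write(f"# r_threshold={network.r_threshold}\t"
                 f"correlation_source={network.correlation_source}\t"
                 f"use_absolute={network.use_absolute}\n")
        for g in network.pool.gene_ids:
            fh.write(g + "\n")


def read_network(prefix) -> GeneNetwork:
    with open(f"{prefix}.nodes.tsv", "rt", encoding="utf-8") as fh:
        header = fh.readline().lstrip("# ").strip()
        meta = dict(item.split("=", 1) for item in header.split("\t"))
        nodes = [line.strip() for line in fh if line.strip()]
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    with open(f"{prefix}.edges.tsv", "rt", encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                a, b = line.split()
                graph.add_edge(a, b)
    return GeneNetwork(
        GenePool(nodes),
        graph,
        float(meta["r_threshold"]),
        meta["correlation_source"],
        meta["use_absolute"] == "True",
    )
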