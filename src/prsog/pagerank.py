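"""PageRank gene importance on the correlation network.

Each undirected edge is expanded into two directed links, the transition
matrix is column-normalized by degree (link weight 1/L(g_j) out of gene j),
and the rank vector solves

    rank = (1 - d)/N + d * M @ rank,

iterated from the uniform vector 1/N until the L1 change between successive
iterates drops below ``tol``.  With damping d in (0, 1) every gene keeps a
teleportation floor of (1 - d)/N, and the converged vector sums to 1.

Isolated ("dangling") genes have no outgoing links; two treatments are
provided.  ``teleport_redistribute`` (default, the standard Google handling)
spreads dangling mass uniformly, preserving the (1 - d)/N floor.
``self_absorb`` lets a dangling gene's mass stay on itself, which pins
isolated genes near the uniform baseline while connected hubs grow past it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .network import GeneNetwork

DANGLING_MODES = ("teleport_redistribute", "self_absorb")


@dataclass(frozen=True)
class PageRankConfig:
    d: float = 0.85
    tol: float = 1e-10
    max_iter: int = 1000
    dangling_mode: str = "teleport_redistribute"

    def validate(self) -> None:
        if not 0.0 < self.d < 1.0:
            raise ValueError(f"damping factor d must lie in (0, 1), got {self.d}")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol must be positive and max_iter >= 1")
        if self.dangling_mode not in DANGLING_MODES:
            raise ValueError(
                f"dangling_mode must be one of {DANGLING_MODES}, "
                f"got {self.dangling_mode!r}"
            )


@dataclass
class RankVector:
    """Per-gene PageRank over the pool; strictly positive, sums to 1."""

    gene_ids: list[str]
    rank: np.ndarray
    iterations_used: int
    converged: bool

    @property
    def n(self) -> int:
        return len(self.gene_ids)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.gene_ids, map(float, self.rank)))

    def __getitem__(self, gene: str) -> float:
        return self.as_dict()[gene]


def pagerank(network: GeneNetwork, config: PageRankConfig | None = None) -> RankVector:
    """Power-iteration PageRank of the gene network (see module docstring)."""
    config = config or PageRankConfig()
    config.validate()
    nodes = network.pool.gene_ids
    n = len(nodes)
    if n < 1:
        raise ValueError("network must contain at least one gene")

    A = nx_adjacency(network)
    deg = np.asarray(A.sum(axis=0)).ravel()
    dangling = deg == 0
    inv_deg = np.where(dangling, 0.0, 1.0 / np.where(dangling, 1.0, deg))
    # column-stochastic transition matrix: column j spreads 1/L(g_j) per link
    M = A @ sp.diags(inv_deg)

    d = config.d
    x = np.full(n, 1.0 / n)
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        flow = M @ x
        if config.dangling_mode == "teleport_redistribute":
            flow = flow + x[dangling].sum() / n
        else:  # self_absorb: dangling mass stays on its own gene
            flow = flow.copy()
            flow[dangling] += x[dangling]
        x_new = (1.0 - d) / n + d * flow
        delta = np.abs(x_new - x).sum()
        x = x_new
        if delta < config.tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"PageRank did not converge in {config.max_iter} iterations "
            f"(last L1 change {delta:.3g}); returning the last iterate",
            stacklevel=2,
        )
    x = x / x.sum()
    return RankVector(list(nodes), x, it, converged)


def nx_adjacency(network: GeneNetwork) -> sp.csr_array:
    """Sparse 0/1 adjacency in pool order (symmetric; both link directions)."""
    import networkx as nx

    return nx.to_scipy_sparse_array(
        network.graph, nodelist=network.pool.gene_ids, weight=None, format="csr"
    ).astype(float)


def pagerank_dense_solve(network: GeneNetwork, config: PageRankConfig | None = None) -> np.ndarray:
    """Exact stationary vector from a dense linear solve.

    Solves (I - d*T) x = (1 - d)/N * 1 where T is the column-stochastic
    transition matrix with the configured dangling handling, then renormalizes.
    Intended as an independent reference for small networks.
    """
    config = config or PageRankConfig()
    config.validate()
    n = network.pool.n
    A = nx_adjacency(network).toarray()
    deg = A.sum(axis=0)
    T = np.zeros_like(A)
    nz = deg > 0
    T[:, nz] = A[:, nz] / deg[nz]
    if config.dangling_mode == "teleport_redistribute":
        T[:, ~nz] = 1.0 / n
    else:
        T[~nz, ~nz] = 1.0
    x = np.linalg.solve(np.eye(n) - config.d * T, np.full(n, (1.0 - config.d) / n))
    return x / x.sum()


def write_ranks(ranks: RankVector, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("gene_id\trank\n")
        for g, v in zip(ranks.gene_ids, ranks.rank):
            fh.write(f"{g}\t{v:.17g}\n")


def read_ranks(path) -> RankVector:
    genes: list[str] = []
    vals: list[float] = []
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline()
        for line in fh:
            if line.strip():
                g, v = line.split("\t")
                genes.append(g)
                vals.append(float(v))
    return RankVector(genes, np.asarray(vals), iterations_used=0, converged=True)
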