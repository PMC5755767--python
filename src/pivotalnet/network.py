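"""Absolute-Pearson co-expression network and hard thresholding.

Similarity between genes i and j is s_ij = |cor(x_i, x_j)| across subjects;
the sign of the correlation is deliberately discarded because only the
strength of the relationship matters here. A hard threshold t binarizes the
weighted network: an edge exists iff s_ij >= t. Scanning t over a grid is
the core device of the whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io import ExpressionMatrix

__all__ = [
    "CorrelationNetwork",
    "ThresholdedGraph",
    "correlation_network",
    "hard_threshold",
    "threshold_grid",
]


@dataclass
class CorrelationNetwork:
    """Symmetric |Pearson| similarity matrix over genes, zero diagonal."""

    gene_ids: list[str]
    sim: np.ndarray

    def __post_init__(self) -> None:
        self.sim = np.asarray(self.sim, dtype=float)
        n = len(self.gene_ids)
        if self.sim.shape != (n, n):
            raise ValueError("similarity matrix shape does not match gene ids")
        if not np.allclose(self.sim, self.sim.T):
            raise ValueError("similarity matrix must be symmetric")
        if (self.sim < 0).any() or (self.sim > 1).any():
            raise ValueError("similarities must lie in [0, 1]")
        if np.diagonal(self.sim).any():
            raise ValueError("diagonal must be zero")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def edges(self) -> list[tuple[str, str, float]]:
        """Weighted edge list over all gene pairs with nonzero similarity."""
        iu, ju = np.triu_indices(self.n_genes, k=1)
        return [
            (self.gene_ids[i], self.gene_ids[j], float(self.sim[i, j]))
            for i, j in zip(iu, ju)
            if self.sim[i, j] > 0
        ]


@dataclass
class ThresholdedGraph:
    """Binary graph at threshold t. Isolated nodes are retained."""

    gene_ids: list[str]
    adj: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.adj = np.asarray(self.adj, dtype=bool)
        n = len(self.gene_ids)
        if self.adj.shape != (n, n):
            raise ValueError("adjacency shape does not match gene ids")
        if (self.adj != self.adj.T).any():
            raise ValueError("adjacency must be symmetric")
        if np.diagonal(self.adj).any():
            raise ValueError("self-loops are not allowed")

    @property
    def n_nodes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adj.sum()) // 2

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.gene_ids)
        iu, ju = np.nonzero(np.triu(self.adj, k=1))
        g.add_edges_from((self.gene_ids[i], self.gene_ids[j]) for i, j in zip(iu, ju))
        return g

    def subgraph(self, genes: set[str]) -> "ThresholdedGraph":
        """Induced subgraph on ``genes`` (order follows the parent graph)."""
        idx = [i for i, g in enumerate(self.gene_ids) if g in genes]
        missing = genes - {self.gene_ids[i] for i in idx}
        if missing:
            raise KeyError(f"gene(s) not in graph: {sorted(missing)}")
        return ThresholdedGraph(
            gene_ids=[self.gene_ids[i] for i in idx],
            adj=self.adj[np.ix_(idx, idx)],
            threshold=self.threshold,
        )


def correlation_network(m: ExpressionMatrix) -> CorrelationNetwork:
    """Build s_ij = |Pearson correlation| between gene expression rows.

    Raises on zero-variance genes (drop them first with
    :func:`pivotalnet.io.drop_zero_variance`).
    """
    if m.n_subjects < 3:
        raise ValueError("need at least 3 subjects for a meaningful correlation")
    sd = m.values.std(axis=1)
    flat = [g for g, s in zip(m.gene_ids, sd) if s == 0]
    if flat:
        raise ValueError(f"zero-variance gene(s): {flat}")
    sim = np.abs(np.corrcoef(m.values))
    # |r| can exceed 1 by rounding; clamp before validating
    np.clip(sim, 0.0, 1.0, out=sim)
    sim = (sim + sim.T) / 2.0
    np.fill_diagonal(sim, 0.0)
    return CorrelationNetwork(gene_ids=list(m.gene_ids), sim=sim)


def hard_threshold(net: CorrelationNetwork, t: float) -> ThresholdedGraph:
    """Binarize the similarity matrix: edge iff s_ij >= t (ties kept)."""
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {t}")
    adj = net.sim >= t
    np.fill_diagonal(adj, False)
    return ThresholdedGraph(gene_ids=list(net.gene_ids), adj=adj, threshold=float(t))


def threshold_grid(start: float = 0.30, stop: float = 0.60, step: float = 0.01) -> list[float]:
    """Inclusive, strictly increasing grid of thresholds (default 0.30–0.60)."""
    if step <= 0:
        raise ValueError("step must be positive")
    n = int(round((stop - start) / step))
    grid = [round(start + k * step, 10) for k in range(n + 1)]
    grid = [t for t in grid if 0.0 <= t <= 1.0 and t <= stop + 1e-12]
    if not grid or any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("grid must be nonempty and strictly increasing")
    return grid
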