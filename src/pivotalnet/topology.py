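"""Topological properties of thresholded graphs and threshold profiles.

Degree, betweenness (Freeman counting: unordered pairs, endpoints excluded,
unnormalized), geodesic distances, diameter and eccentricity. On the
disconnected graphs that high thresholds inevitably produce, diameter and
eccentricity are taken over finite distances only, with isolated nodes at
eccentricity 0, so that threshold profiles stay finite everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network import CorrelationNetwork, ThresholdedGraph, hard_threshold

__all__ = [
    "TopologySummary",
    "degree",
    "strength",
    "betweenness",
    "geodesics",
    "diameter",
    "eccentricity",
    "topology_profile",
]


@dataclass(frozen=True)
class TopologySummary:
    """Per-threshold averages over all nodes (isolated nodes included)."""

    threshold: float
    mean_degree: float
    mean_betweenness: float
    diameter: int
    mean_eccentricity: float
    n_nodes: int
    n_edges: int


def degree(g: ThresholdedGraph) -> np.ndarray:
    """Number of neighbors per node, in gene-id order."""
    return g.adj.sum(axis=1).astype(int)


def strength(net: CorrelationNetwork) -> np.ndarray:
    """Weighted degree: sum of similarities to all other genes."""
    return net.sim.sum(axis=1)


def betweenness(g: ThresholdedGraph | nx.Graph) -> np.ndarray:
    """Freeman betweenness b_i = sum over pairs j<k of n_jk(i)/n_jk.

    Unnormalized, endpoints excluded; pairs in different components
    contribute nothing.
    """
    if isinstance(g, ThresholdedGraph):
        order = g.gene_ids
        gx = g.to_networkx()
    else:
        gx = g
        order = list(gx.nodes)
    bc = nx.betweenness_centrality(gx, normalized=False)
    return np.array([bc[v] for v in order], dtype=float)


def geodesics(g: ThresholdedGraph) -> np.ndarray:
    """All-pairs shortest-path length matrix; inf across components."""
    gx = g.to_networkx()
    n = g.n_nodes
    idx = {v: i for i, v in enumerate(g.gene_ids)}
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for src, lengths in nx.all_pairs_shortest_path_length(gx):
        for dst, ln in lengths.items():
            d[idx[src], idx[dst]] = ln
    return d


def diameter(g: ThresholdedGraph) -> int:
    """Maximum finite geodesic; 0 for an edgeless (or empty-pair) graph."""
    if g.n_nodes == 0:
        raise ValueError("empty graph")
    d = geodesics(g)
    finite = d[np.isfinite(d)]
    return int(finite.max()) if finite.size else 0


def eccentricity(g: ThresholdedGraph) -> np.ndarray:
    """Per-node maximum finite geodesic (0 for isolated nodes)."""
    if g.n_nodes == 0:
        raise ValueError("empty graph")
    d = geodesics(g)
    d = np.where(np.isfinite(d), d, 0.0)
    return d.max(axis=1).astype(int)


def summarize(g: ThresholdedGraph) -> TopologySummary:
    """Averages of the scanned properties for one thresholded graph."""
    n = g.n_nodes
    return TopologySummary(
        threshold=g.threshold,
        mean_degree=float(degree(g).mean()),
        mean_betweenness=float(betweenness(g).mean()),
        diameter=diameter(g),
        mean_eccentricity=float(eccentricity(g).mean()),
        n_nodes=n,
        n_edges=g.n_edges,
    )


def topology_profile(
    net: CorrelationNetwork, grid: list[float]
) -> list[TopologySummary]:
    """One :class:`TopologySummary` per threshold of the grid."""
    return [summarize(hard_threshold(net, t)) for t in grid]
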