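"""Shannon entropy of the betweenness distribution, per node.

The betweenness vector of a graph is rescaled to a probability mass
p_i = b_i / sum(b) and fed into Shannon's formula H = -sum p_i log2 p_i,
then divided by the node count so communities of different sizes are
comparable. A graph whose shortest paths are spread over many nodes (high
entropy) carries more structural information than one dominated by a few
intermediaries; scanning H per node across thresholds independently
confirms the threshold chosen by the PMI.

A ``literal=True`` switch feeds the raw (unnormalized) betweenness values
into the log instead, for comparison; that variant is not a true Shannon
entropy and can go negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .communities import detect_communities, target_community
from .network import CorrelationNetwork, ThresholdedGraph, hard_threshold
from .topology import betweenness

__all__ = ["EntropyRecord", "betweenness_entropy", "entropy_scan"]


@dataclass(frozen=True)
class EntropyRecord:
    threshold: float
    h_network_per_node: float
    h_community_per_node: float | None
    n_network: int
    n_community: int


def betweenness_entropy(g: ThresholdedGraph, literal: bool = False) -> float:
    """Entropy of the betweenness mass, in bits per node.

    All-zero betweenness (e.g. a complete graph, where no shortest path has
    an intermediary) gives 0 by the 0*log 0 := 0 convention.
    """
    if g.n_nodes == 0:
        raise ValueError("empty graph")
    b = betweenness(g)
    total = b.sum()
    if total == 0:
        return 0.0
    if literal:
        pos = b[b > 0]
        h = -float(np.sum(pos * np.log2(pos)))
    else:
        p = b / total
        p = p[p > 0]
        h = -float(np.sum(p * np.log2(p)))
    return h / g.n_nodes


def entropy_scan(
    net: CorrelationNetwork,
    grid: Sequence[float],
    target: str = "DRD2",
    method: str = "fast_greedy",
    seed: int = 0,
    literal: bool = False,
) -> list[EntropyRecord]:
    """Per-threshold entropy of the whole network and of the target community.

    The community entropy is computed on the subgraph induced by the target
    community found with ``method``; it is None when that community is a
    single node.
    """
    if target not in net.gene_ids:
        raise KeyError(f"target gene {target!r} not in network")
    records = []
    for t in grid:
        g = hard_threshold(net, t)
        h_net = betweenness_entropy(g, literal=literal)
        comm = target_community(detect_communities(g, method, seed=seed), target)
        if comm.size >= 2:
            h_comm = betweenness_entropy(g.subgraph(set(comm.members)), literal=literal)
        else:
            h_comm = None
        records.append(
            EntropyRecord(
                threshold=float(t),
                h_network_per_node=h_net,
                h_community_per_node=h_comm,
                n_network=g.n_nodes,
                n_community=comm.size,
            )
        )
    return records
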