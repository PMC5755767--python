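"""Community detection on thresholded graphs.

Four detectors spanning the main families in use for co-expression graphs:
fast greedy and Louvain (modularity optimization), walktrap (random-walk
similarity, agglomerative) and infomap (map equation / mutual information).
All four are delegated to igraph behind a single deterministic contract:
``detect_communities(graph, method, seed)`` always returns the same
partition for the same arguments. Isolated nodes become singleton
communities.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import igraph as ig
import numpy as np

from .network import ThresholdedGraph

__all__ = [
    "METHODS",
    "Partition",
    "TargetCommunity",
    "modularity",
    "detect_communities",
    "target_community",
]

METHODS = ("fast_greedy", "louvain", "walktrap", "infomap")

# stochastic detectors: run several seeded trials and keep the best partition
INFOMAP_TRIALS = 10
LOUVAIN_RESTARTS = 10


@dataclass(frozen=True)
class Partition:
    """A full node partition: every gene carries exactly one community id,
    ids contiguous from 0 in order of first appearance."""

    method: str
    labels: dict[str, int]
    threshold: float
    seed: int

    def community_of(self, gene: str) -> int:
        return self.labels[gene]

    def communities(self) -> list[set[str]]:
        out: dict[int, set[str]] = {}
        for g, c in self.labels.items():
            out.setdefault(c, set()).add(g)
        return [out[c] for c in sorted(out)]


@dataclass(frozen=True)
class TargetCommunity:
    """The community containing the target gene at one threshold."""

    target_gene: str
    members: frozenset[str]
    threshold: float
    method: str

    @property
    def size(self) -> int:
        return len(self.members)


def modularity(g: ThresholdedGraph, p: Partition) -> float:
    """Newman–Girvan modularity Q = sum_c [e_c/m - (d_c/2m)^2].

    e_c = intra-community edge count, d_c = total degree in community c,
    m = total edges. Requires at least one edge.
    """
    m = g.n_edges
    if m == 0:
        raise ValueError("modularity is undefined on an edgeless graph")
    missing = [v for v in g.gene_ids if v not in p.labels]
    if missing:
        raise ValueError(f"partition does not label node(s): {missing}")
    labels = np.array([p.labels[v] for v in g.gene_ids])
    deg = g.adj.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        mask = labels == c
        e_c = g.adj[np.ix_(mask, mask)].sum() / 2
        d_c = deg[mask].sum()
        q += e_c / m - (d_c / (2 * m)) ** 2
    return float(q)


def _to_igraph(g: ThresholdedGraph) -> ig.Graph:
    iu, ju = np.nonzero(np.triu(g.adj, k=1))
    return ig.Graph(n=g.n_nodes, edges=list(zip(iu.tolist(), ju.tolist())))


def _canonical_labels(gene_ids: list[str], membership: list[int]) -> dict[str, int]:
    # relabel community ids contiguously in order of first appearance
    remap: dict[int, int] = {}
    labels: dict[str, int] = {}
    for gene, raw in zip(gene_ids, membership):
        if raw not in remap:
            remap[raw] = len(remap)
        labels[gene] = remap[raw]
    return labels


def detect_communities(g: ThresholdedGraph, method: str, seed: int = 0) -> Partition:
    """Partition ``g`` with one of the four detectors, reproducibly.

    The igraph random number generator is re-seeded from ``seed`` on every
    call, so stochastic detectors (louvain node order, infomap trials) are
    deterministic given (graph, method, seed). An edgeless graph yields all
    singletons for every method.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if g.n_edges == 0:
        membership = list(range(g.n_nodes))
    else:
        graph = _to_igraph(g)
        ig.set_random_number_generator(random.Random(seed))
        try:
            if method == "fast_greedy":
                membership = graph.community_fastgreedy().as_clustering().membership
            elif method == "louvain":
                # node order is random: take the best-modularity of several
                # seeded restarts (same convention as infomap's trials)
                best = None
                for _ in range(LOUVAIN_RESTARTS):
                    cl = graph.community_multilevel()
                    if best is None or cl.modularity > best.modularity:
                        best = cl
                membership = best.membership
            elif method == "walktrap":
                membership = graph.community_walktrap().as_clustering().membership
            else:  # infomap
                membership = graph.community_infomap(trials=INFOMAP_TRIALS).membership
        finally:
            ig.set_random_number_generator(random._inst)
    return Partition(
        method=method,
        labels=_canonical_labels(g.gene_ids, list(membership)),
        threshold=g.threshold,
        seed=seed,
    )


def target_community(p: Partition, target: str) -> TargetCommunity:
    """Extract the member set of the community containing ``target``."""
    if target not in p.labels:
        raise KeyError(f"target gene {target!r} not in partition")
    cid = p.labels[target]
    members = frozenset(g for g, c in p.labels.items() if c == cid)
    return TargetCommunity(
        target_gene=target, members=members, threshold=p.threshold, method=p.method
    )
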