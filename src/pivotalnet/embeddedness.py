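"""Embeddedness of the target gene and hub-gene analysis.

How strongly is the target tied to its detected community, versus the whole
module and versus chance? The statistic is the target's strength per node:
the sum of its unthresholded |r| similarities to the other members of a
gene set, divided by the set size. The null draws communities of the same
size at random (target plus size-1 random genes) and records the mean and
standard deviation of the statistic. Hub genes are those whose scaled
strength (strength / max strength over the network) exceeds a cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .network import CorrelationNetwork
from .topology import strength

__all__ = [
    "StrengthReport",
    "HubTable",
    "target_strength_per_node",
    "random_community_null",
    "hub_table",
    "hub_overlap",
]

HUB_CUTOFF = 0.70


@dataclass(frozen=True)
class StrengthReport:
    strength_per_node_network: float
    strength_per_node_community: float
    null_mean: float
    null_sd: float
    n_null: int


@dataclass(frozen=True)
class HubTable:
    """Rows (gene, strength, scaled strength) sorted by descending strength,
    restricted to scaled strength strictly above ``cutoff``."""

    rows: tuple[tuple[str, float, float], ...]
    cutoff: float

    @property
    def genes(self) -> list[str]:
        return [g for g, _, _ in self.rows]


def target_strength_per_node(
    net: CorrelationNetwork, gene_set: Iterable[str], target: str
) -> float:
    """Sum of target's similarities within ``gene_set``, over the set size.

    Uses the weighted, unthresholded similarity network; the target itself
    contributes nothing (zero diagonal) but counts in the divisor.
    """
    members = set(gene_set)
    if target not in members:
        raise KeyError(f"target {target!r} not in gene set")
    if len(members) < 2:
        raise ValueError("gene set must contain the target plus at least one gene")
    idx = {g: i for i, g in enumerate(net.gene_ids)}
    missing = members - idx.keys()
    if missing:
        raise KeyError(f"gene(s) not in network: {sorted(missing)}")
    ti = idx[target]
    # iterate in network order so the float sum is reproducible
    total = sum(net.sim[ti, i] for i, g in enumerate(net.gene_ids)
                if g in members and g != target)
    return float(total) / len(members)


def random_community_null(
    net: CorrelationNetwork,
    target: str,
    size: int,
    n_reps: int = 1000,
    seed: int = 0,
    pool: Sequence[str] | None = None,
) -> tuple[float, float, np.ndarray]:
    """Strength-per-node null from random communities of the given size.

    Each replicate is the target plus ``size - 1`` genes drawn without
    replacement from ``pool`` (default: every other gene in the network).
    Returns (mean, sd, replicate values); deterministic per seed.
    """
    if size < 2:
        raise ValueError("null community size must be at least 2")
    if pool is None:
        pool = [g for g in net.gene_ids if g != target]
    else:
        pool = [g for g in pool if g != target]
    if len(pool) < size - 1:
        raise ValueError(
            f"pool of {len(pool)} genes cannot fill communities of size {size}"
        )
    rng = np.random.default_rng(seed)
    pool_arr = np.array(pool)
    samples = np.empty(n_reps)
    for r in range(n_reps):
        draw = rng.choice(pool_arr, size=size - 1, replace=False)
        samples[r] = target_strength_per_node(net, {target, *draw}, target)
    return float(samples.mean()), float(samples.std()), samples


def hub_table(net: CorrelationNetwork, cutoff: float = HUB_CUTOFF) -> HubTable:
    """Genes with scaled strength strictly above ``cutoff``.

    Scaled strength divides each gene's strength by the maximum strength in
    the network, so the strongest gene always scores exactly 1.
    """
    s = strength(net)
    if net.n_genes == 0:
        raise ValueError("empty network")
    smax = s.max()
    scaled = s / smax if smax > 0 else np.ones_like(s)
    rows = [
        (g, float(si), float(sc))
        for g, si, sc in zip(net.gene_ids, s, scaled)
        if sc > cutoff
    ]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return HubTable(rows=tuple(rows), cutoff=cutoff)


def hub_overlap(hubs: HubTable, community: Iterable[str]) -> float:
    """Fraction of hub genes that belong to the community."""
    if not hubs.rows:
        raise ValueError("hub table is empty")
    comm = set(community)
    return sum(g in comm for g in hubs.genes) / len(hubs.rows)
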