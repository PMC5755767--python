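"""Dice-index machinery: cross-method concordance and threshold stability.

Dice(A, B) = 2|A∩B| / (|A|+|B|) compares two gene communities: 1 means
identical membership, 0 means disjoint. Two uses: (i) agreement of the four
detectors at the chosen threshold, against a reference method; (ii)
stability of the target community across a threshold neighborhood, each
threshold's community compared with the one at the selected threshold T.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .communities import METHODS, detect_communities, target_community
from .io import ExpressionMatrix
from .network import CorrelationNetwork, hard_threshold
from .pmi import DEFAULT_MIN_SIZE, _derive_seed

__all__ = ["DiceRecord", "ConcordanceRow", "dice", "method_concordance", "dice_scan"]


@dataclass(frozen=True)
class DiceRecord:
    threshold: float
    dice: float | None  # None when the community at this threshold is degenerate
    size: int
    q_low: float | None = None
    q_high: float | None = None


@dataclass(frozen=True)
class ConcordanceRow:
    method: str
    size: int
    size_q25: float | None
    size_q75: float | None
    dice_vs_reference: float | None
    members: frozenset[str]


def dice(a: Iterable[str], b: Iterable[str]) -> float:
    """Dice overlap of two gene sets; errors when both are empty."""
    sa, sb = set(a), set(b)
    if not sa and not sb:
        raise ValueError("Dice index is undefined for two empty sets")
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


def method_concordance(
    net: CorrelationNetwork,
    t: float,
    methods: Sequence[str] = METHODS,
    target: str = "DRD2",
    seed: int = 0,
    reference: str = "fast_greedy",
    expr: ExpressionMatrix | None = None,
    n_boot: int = 0,
) -> list[ConcordanceRow]:
    """Target-community size and Dice vs the reference method at threshold t.

    With ``expr`` and ``n_boot`` the size column gains a bootstrap
    interquartile spread (subject resampling, as for the PMI bands).
    """
    if reference not in methods:
        raise ValueError(f"reference {reference!r} must be one of {methods}")
    g = hard_threshold(net, t)
    comms = {
        m: target_community(detect_communities(g, m, seed=seed), target)
        for m in methods
    }
    ref_members = comms[reference].members
    rows = []
    for m in methods:
        members = comms[m].members
        q25 = q75 = None
        if expr is not None and n_boot > 0:
            sizes = _bootstrap_sizes(expr, t, m, target, n_boot, _derive_seed(seed, t, m))
            if sizes:
                q25, q75 = (float(q) for q in np.percentile(sizes, [25, 75]))
        rows.append(
            ConcordanceRow(
                method=m,
                size=len(members),
                size_q25=q25,
                size_q75=q75,
                dice_vs_reference=dice(members, ref_members) if members else None,
                members=members,
            )
        )
    return rows


def _bootstrap_sizes(
    m: ExpressionMatrix, t: float, method: str, target: str, n_boot: int, seed: int
) -> list[int]:
    from .network import correlation_network  # local to avoid cycle at import time

    rng = np.random.default_rng(seed)
    sizes: list[int] = []
    for _ in range(n_boot):
        cols = rng.integers(0, m.n_subjects, size=m.n_subjects)
        vals = m.values[:, cols]
        keep = vals.std(axis=1) > 0
        if keep.sum() < 3 or not keep[m.gene_ids.index(target)]:
            continue
        rep = ExpressionMatrix(
            gene_ids=[g for g, k in zip(m.gene_ids, keep) if k],
            subject_ids=[f"b{j}" for j in range(m.n_subjects)],
            values=vals[keep],
        )
        g = hard_threshold(correlation_network(rep), t)
        det_seed = int(rng.integers(0, 2**31))
        comm = target_community(detect_communities(g, method, seed=det_seed), target)
        sizes.append(comm.size)
    return sizes


def dice_scan(
    net: CorrelationNetwork,
    best_t: float,
    grid: Sequence[float],
    method: str = "fast_greedy",
    target: str = "DRD2",
    seed: int = 0,
    min_size: int = DEFAULT_MIN_SIZE,
) -> list[DiceRecord]:
    """Dice of the community at each grid threshold vs the one at ``best_t``.

    A record is flagged (``dice=None``) when the community at that threshold
    falls below ``min_size``; the reference community at ``best_t`` must be
    valid or the scan errors out.
    """
    g_ref = hard_threshold(net, best_t)
    ref = target_community(detect_communities(g_ref, method, seed=seed), target)
    if ref.size < min_size:
        raise ValueError(
            f"community at reference threshold {best_t} has only {ref.size} gene(s)"
        )
    records = []
    for t in grid:
        g = hard_threshold(net, t)
        comm = target_community(detect_communities(g, method, seed=seed), target)
        value = dice(comm.members, ref.members) if comm.size >= min_size else None
        records.append(DiceRecord(threshold=float(t), dice=value, size=comm.size))
    return records
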