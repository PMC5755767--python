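"""Independent brute-force oracles used to check the graph machinery.

Everything here is deliberately naive — Floyd–Warshall distances, explicit
geodesic enumeration by depth-first search, pair-sum modularity, exhaustive
set partitions, closed-form weighted least squares — and shares no code
with the implementation under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from pivotalnet import ThresholdedGraph


def make_graph(names: list[str], edges: list[tuple[str, str]], t: float = 0.5) -> ThresholdedGraph:
    """Build a ThresholdedGraph from an explicit edge list."""
    idx = {g: i for i, g in enumerate(names)}
    adj = np.zeros((len(names), len(names)), dtype=bool)
    for a, b in edges:
        adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = True
    return ThresholdedGraph(gene_ids=list(names), adj=adj, threshold=t)


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.where(adj, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def geodesic_paths(adj: np.ndarray, j: int, k: int) -> list[tuple[int, ...]]:
    """All shortest paths from j to k, as node tuples (inclusive)."""
    d = floyd_warshall(adj)
    if not math.isfinite(d[j, k]):
        return []
    target_len = int(d[j, k])
    paths: list[tuple[int, ...]] = []

    def extend(path: tuple[int, ...]) -> None:
        cur = path[-1]
        if cur == k:
            paths.append(path)
            return
        remaining = target_len - (len(path) - 1)
        for nxt in np.nonzero(adj[cur])[0]:
            if d[nxt, k] == remaining - 1:
                extend(path + (int(nxt),))

    extend((j,))
    return paths


def betweenness_oracle(adj: np.ndarray) -> np.ndarray:
    """Freeman betweenness by explicit geodesic enumeration."""
    n = adj.shape[0]
    b = np.zeros(n)
    for j, k in itertools.combinations(range(n), 2):
        paths = geodesic_paths(adj, j, k)
        if not paths:
            continue
        for i in range(n):
            if i in (j, k):
                continue
            through = sum(1 for p in paths if i in p)
            b[i] += through / len(paths)
    return b


def eccentricity_oracle(adj: np.ndarray) -> np.ndarray:
    d = floyd_warshall(adj)
    d = np.where(np.isfinite(d), d, 0.0)
    return d.max(axis=1)


def diameter_oracle(adj: np.ndarray) -> int:
    d = floyd_warshall(adj)
    finite = d[np.isfinite(d)]
    return int(finite.max()) if finite.size else 0


def modularity_oracle(adj: np.ndarray, labels: np.ndarray) -> float:
    """Pair-sum form: Q = (1/2m) sum_ij (A_ij - k_i k_j / 2m) delta(c_i, c_j)."""
    k = adj.sum(axis=1).astype(float)
    two_m = k.sum()
    same = np.asarray(labels)[:, None] == np.asarray(labels)[None, :]
    return float(((adj - np.outer(k, k) / two_m) * same).sum() / two_m)


def entropy_oracle(adj: np.ndarray) -> float:
    """Bits per node of the normalized-betweenness Shannon entropy."""
    b = betweenness_oracle(adj)
    total = b.sum()
    if total == 0:
        return 0.0
    p = b[b > 0] / total
    return float(-(p * np.log2(p)).sum()) / adj.shape[0]


def set_partitions(items: list):
    """Yield every partition of ``items`` as a list of lists."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def wls_closed_form(t: np.ndarray, y: np.ndarray, err: np.ndarray) -> tuple[float, float]:
    """(intercept, slope) from the weighted normal equations."""
    w = 1.0 / err**2
    s = w.sum()
    sx, sy = (w * t).sum(), (w * y).sum()
    sxx, sxy = (w * t * t).sum(), (w * t * y).sum()
    delta = s * sxx - sx * sx
    return (sxx * sy - sx * sxy) / delta, (s * sxy - sx * sy) / delta
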