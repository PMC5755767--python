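"""Pivotal Module Index: the composite score driving threshold selection.

For the community C containing the target gene at threshold t,

    PMI = (mean degree of C) * (mean betweenness of C) / (diameter of C * |C|)

with degree and betweenness averaged over C's nodes on the subgraph induced
by C (a ``scope`` switch measures them in the whole thresholded network
instead). High degree and betweenness flag intense, strategically placed
links; a small diameter and size reward cohesion — so the PMI peaks at
thresholds where the target sits in a tight, strategic community.

Statistical error bands come from a subject bootstrap: resample subjects
with replacement, rebuild the correlation network, re-detect, recompute the
PMI, and take the 25th–75th percentile range of the replicate distribution.
A weighted linear fit of the threshold profile then flags thresholds whose
PMI rises significantly above the linear trend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .communities import METHODS, TargetCommunity, detect_communities, target_community
from .io import ExpressionMatrix
from .network import CorrelationNetwork, ThresholdedGraph, correlation_network, hard_threshold
from .topology import betweenness, degree, diameter

__all__ = [
    "PMIUndefinedError",
    "PMIRecord",
    "BootstrapSummary",
    "TrendFit",
    "pmi",
    "pmi_scan",
    "bootstrap_pmi",
    "select_best_threshold",
    "pmi_trend_test",
]

DEFAULT_MIN_SIZE = 3  # a community needs at least three genes to be one


class PMIUndefinedError(ValueError):
    """Community too small or degenerate for the index to be defined."""


@dataclass(frozen=True)
class PMIRecord:
    """Scan entry for one (threshold, method) cell; ``pmi`` is None when the
    target community fell below the minimum size or was degenerate."""

    threshold: float
    method: str
    pmi: float | None
    size: int
    q25: float | None = None
    q75: float | None = None

    @property
    def valid(self) -> bool:
        return self.pmi is not None


@dataclass(frozen=True)
class BootstrapSummary:
    """Percentile band of the PMI bootstrap distribution."""

    q25: float
    q75: float
    median: float
    n_valid: int
    n_boot: int
    values: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class TrendFit:
    """Weighted linear fit of mean PMI vs threshold with a 95% band."""

    slope: float
    intercept: float
    chi2_reduced: float
    thresholds: tuple[float, ...]
    fitted: tuple[float, ...]
    ci_lower: tuple[float, ...]
    ci_upper: tuple[float, ...]
    flagged: tuple[float, ...]
    excess_at_best: bool


def pmi(g: ThresholdedGraph, c: TargetCommunity, scope: str = "induced") -> float:
    """Compute the index for community ``c`` within graph ``g``.

    ``scope='induced'`` (default) measures degree and betweenness on the
    subgraph induced by the community; ``scope='global'`` measures them for
    the community's nodes in the whole thresholded network. The diameter is
    always that of the induced subgraph (per-component maximum when it is
    disconnected).
    """
    if scope not in ("induced", "global"):
        raise ValueError(f"scope must be 'induced' or 'global', got {scope!r}")
    members = set(c.members)
    if len(members) < 2:
        raise PMIUndefinedError(f"community of size {len(members)} has no structure")
    sub = g.subgraph(members)
    d_tc = diameter(sub)
    if d_tc == 0:
        raise PMIUndefinedError("induced subgraph has no edges (zero diameter)")
    if scope == "induced":
        k_tc = float(degree(sub).mean())
        b_tc = float(betweenness(sub).mean())
    else:
        idx = [i for i, gid in enumerate(g.gene_ids) if gid in members]
        k_tc = float(degree(g)[idx].mean())
        b_tc = float(betweenness(g)[idx].mean())
    n_tc = len(members)
    return (k_tc * b_tc) / (d_tc * n_tc)


def _cell(
    net: CorrelationNetwork,
    t: float,
    method: str,
    target: str,
    min_size: int,
    seed: int,
    scope: str,
    max_size: int | None = None,
) -> tuple[float | None, int]:
    """Point-estimate PMI and community size for one scan cell."""
    g = hard_threshold(net, t)
    part = detect_communities(g, method, seed=seed)
    comm = target_community(part, target)
    if comm.size < min_size or (max_size is not None and comm.size > max_size):
        return None, comm.size
    try:
        return pmi(g, comm, scope=scope), comm.size
    except PMIUndefinedError:
        return None, comm.size


def pmi_scan(
    net: CorrelationNetwork,
    grid: Sequence[float],
    methods: Sequence[str] = METHODS,
    target: str = "DRD2",
    min_size: int = DEFAULT_MIN_SIZE,
    seed: int = 0,
    scope: str = "induced",
    expr: ExpressionMatrix | None = None,
    n_boot: int = 0,
    max_size: int | None = None,
) -> list[PMIRecord]:
    """PMI over the full threshold x method grid.

    Cells whose target community has fewer than ``min_size`` genes, more
    than ``max_size`` (a community swallowing most of the network is no
    community at all), or no internal edges are emitted flagged
    (``pmi=None``) rather than dropped. When ``expr`` and ``n_boot`` are
    given, each valid cell also carries the bootstrap 25th/75th percentile
    band.
    """
    if target not in net.gene_ids:
        raise KeyError(f"target gene {target!r} not in network")
    records: list[PMIRecord] = []
    for t in grid:
        for method in methods:
            value, size = _cell(net, t, method, target, min_size, seed, scope, max_size)
            q25 = q75 = None
            if value is not None and expr is not None and n_boot > 0:
                boot_seed = _derive_seed(seed, t, method)
                try:
                    bs = bootstrap_pmi(
                        expr, t, method, target,
                        n_boot=n_boot, seed=boot_seed,
                        min_size=min_size, scope=scope, max_size=max_size,
                    )
                    q25, q75 = bs.q25, bs.q75
                except ValueError:
                    pass  # all replicates degenerate: leave the band empty
            records.append(
                PMIRecord(threshold=float(t), method=method, pmi=value,
                          size=size, q25=q25, q75=q75)
            )
    return records


def _derive_seed(seed: int, t: float, method: str) -> int:
    ss = np.random.SeedSequence([seed, int(round(t * 1000)), METHODS.index(method)])
    return int(ss.generate_state(1)[0] % (2**31))


def bootstrap_pmi(
    m: ExpressionMatrix,
    t: float,
    method: str,
    target: str,
    n_boot: int = 1000,
    seed: int = 0,
    min_size: int = DEFAULT_MIN_SIZE,
    scope: str = "induced",
    max_size: int | None = None,
) -> BootstrapSummary:
    """Subject bootstrap of the PMI at one (threshold, method) cell.

    Subjects (columns) are resampled with replacement ``n_boot`` times; each
    replicate rebuilds the |r| network, re-thresholds, re-detects and
    recomputes the PMI. Replicates whose target community collapses below
    ``min_size`` (or degenerates) contribute nothing to the percentiles.
    """
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    rng = np.random.default_rng(seed)
    values: list[float] = []
    for _ in range(n_boot):
        cols = rng.integers(0, m.n_subjects, size=m.n_subjects)
        vals = m.values[:, cols]
        sd = vals.std(axis=1)
        keep = sd > 0
        if keep.sum() < 3 or not keep[m.gene_ids.index(target)]:
            continue
        rep = ExpressionMatrix(
            gene_ids=[g for g, k in zip(m.gene_ids, keep) if k],
            subject_ids=[f"b{j}" for j in range(m.n_subjects)],
            values=vals[keep],
        )
        net = correlation_network(rep)
        det_seed = int(rng.integers(0, 2**31))
        value, _ = _cell(net, t, method, target, min_size, det_seed, scope, max_size)
        if value is not None:
            values.append(value)
    if not values:
        raise ValueError("all bootstrap replicates were degenerate")
    arr = np.asarray(values)
    q25, med, q75 = np.percentile(arr, [25, 50, 75])
    return BootstrapSummary(
        q25=float(q25), q75=float(q75), median=float(med),
        n_valid=len(values), n_boot=n_boot, values=arr,
    )


def select_best_threshold(
    records: Sequence[PMIRecord],
    methods: Sequence[str] = METHODS,
    window: tuple[float, float] | None = None,
) -> float:
    """Argmax of the cross-method mean PMI.

    Only thresholds where every method yields a valid community compete;
    ``window`` (inclusive bounds, typically the range where the topological
    properties peak) restricts the candidates further. Ties break toward
    the lower threshold (the denser, more inclusive network).
    """
    by_t: dict[float, dict[str, float]] = {}
    for r in records:
        if r.valid:
            by_t.setdefault(r.threshold, {})[r.method] = r.pmi  # type: ignore[arg-type]
    candidates = [
        (t, np.mean([vals[m] for m in methods]))
        for t, vals in sorted(by_t.items())
        if all(m in vals for m in methods)
        and (window is None or window[0] - 1e-9 <= t <= window[1] + 1e-9)
    ]
    if not candidates:
        raise ValueError("no threshold yields a valid community for every method")
    best_t, best = candidates[0]
    for t, mean in candidates[1:]:
        if mean > best:  # strict: ties keep the lower threshold
            best_t, best = t, mean
    return best_t


def pmi_trend_test(
    avg_profile: Sequence[tuple[float, float, float]],
    best_t: float | None = None,
) -> TrendFit:
    """Weighted linear fit of (threshold, mean PMI, error) points.

    Weights are 1/error^2; the reduced chi-square measures fit quality.
    A threshold is flagged as an excess when its PMI lies above the upper
    95% confidence band of the fitted line and more than 1.96 of its own
    errors above the fit — the signature of a threshold that outperforms
    the overall linear trend.
    """
    pts = [(t, y, e) for t, y, e in avg_profile if np.isfinite(y) and np.isfinite(e)]
    if len(pts) < 3:
        raise ValueError("need at least 3 finite points to fit a trend")
    t = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    err = np.array([max(p[2], 1e-12) for p in pts])  # guard exact-zero errors
    x = sm.add_constant(t)
    res = sm.WLS(y, x, weights=1.0 / err**2).fit()
    intercept, slope = res.params
    fitted = res.fittedvalues
    chi2 = float(np.sum(((y - fitted) / err) ** 2))
    chi2_reduced = chi2 / (len(pts) - 2)
    # parameter covariance with known per-point errors (not rescaled by fit scatter)
    ncov = np.asarray(res.normalized_cov_params)
    se_fit = np.sqrt(np.einsum("ij,jk,ik->i", x, ncov, x))
    upper = fitted + 1.96 * se_fit
    lower = fitted - 1.96 * se_fit
    flagged = tuple(
        float(ti)
        for ti, yi, ei, fi, ui in zip(t, y, err, fitted, upper)
        if yi > ui and (yi - fi) > 1.96 * ei
    )
    return TrendFit(
        slope=float(slope),
        intercept=float(intercept),
        chi2_reduced=float(chi2_reduced),
        thresholds=tuple(float(v) for v in t),
        fitted=tuple(float(v) for v in fitted),
        ci_lower=tuple(float(v) for v in lower),
        ci_upper=tuple(float(v) for v in upper),
        flagged=flagged,
        excess_at_best=(best_t is not None and any(np.isclose(best_t, f) for f in flagged)),
    )
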