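"""End-to-end orchestration: network, scans, threshold choice, validation.

Stages run in the order the method prescribes: correlation network ->
topology profile -> PMI scan with bootstrap bands -> linear-trend excess
test -> entropy scan -> threshold choice -> cross-method concordance ->
Dice stability -> embeddedness (strength vs random null) -> hub genes.

The topology profile does double duty: the thresholds at which the three
non-monotonic network properties (mean betweenness, diameter, mean
eccentricity) peak bracket the optimal range, and the threshold choice —
argmax of the cross-method mean PMI over thresholds where every method
yields a valid community — is made inside that range (falling back to the
whole grid when the range holds no fully valid threshold). The entropy
argmax over the same candidate range serves as confirmation; when it
disagrees with the PMI choice by more than one grid step the PMI wins and
the disagreement is logged.

A single global seed expands deterministically into per-stage seeds, so a
rerun with the same config reproduces every output byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import io as pio
from .communities import METHODS, detect_communities, target_community
from .embeddedness import (
    HUB_CUTOFF,
    HubTable,
    StrengthReport,
    hub_overlap,
    hub_table,
    random_community_null,
    target_strength_per_node,
)
from .entropy import EntropyRecord, entropy_scan
from .network import CorrelationNetwork, correlation_network, hard_threshold, threshold_grid
from .pmi import (
    DEFAULT_MIN_SIZE,
    PMIRecord,
    TrendFit,
    pmi_scan,
    pmi_trend_test,
    select_best_threshold,
)
from .stability import ConcordanceRow, DiceRecord, dice_scan, method_concordance
from .topology import TopologySummary, topology_profile

__all__ = ["PipelineConfig", "PipelineReport", "PipelineError", "run_pipeline", "write_report"]

log = logging.getLogger("pivotalnet")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    expression: str | None = None
    metadata: str | None = None
    target: str = "DRD2"
    grid_start: float = 0.30
    grid_stop: float = 0.60
    grid_step: float = 0.01
    methods: tuple[str, ...] = METHODS
    reference_method: str = "fast_greedy"
    min_size: int = DEFAULT_MIN_SIZE
    n_boot: int = 1000
    null_reps: int = 1000
    hub_cutoff: float = HUB_CUTOFF
    min_rin: float = 7.0
    allowed_groups: tuple[str, ...] | None = None
    scope: str = "induced"
    max_size_frac: float = 0.5  # a community larger than this network fraction is no community
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown key(s) {sorted(unknown)}")
        for key in ("methods", "allowed_groups"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def grid(self) -> list[float]:
        return threshold_grid(self.grid_start, self.grid_stop, self.grid_step)


@dataclass
class PipelineReport:
    config: PipelineConfig
    topology: list[TopologySummary]
    pmi_records: list[PMIRecord]
    trend: TrendFit | None
    entropy: list[EntropyRecord]
    best_threshold: float
    optimal_range: tuple[float, float]
    entropy_argmax: float
    entropy_confirms: bool
    community: frozenset[str]
    concordance: list[ConcordanceRow]
    dice_profile: list[DiceRecord]
    strengths: StrengthReport
    hubs: HubTable
    hub_overlap_fraction: float
    network: CorrelationNetwork = field(repr=False)


def _stage_seeds(seed: int, n: int = 4) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def run_pipeline(
    cfg: PipelineConfig, expr: pio.ExpressionMatrix | None = None
) -> PipelineReport:
    """Run every stage on ``expr`` (or the configured expression file)."""
    det_seed, boot_seed, null_seed, _ = _stage_seeds(cfg.seed)
    grid = cfg.grid()

    try:
        if expr is None:
            if cfg.expression is None:
                raise ValueError("no expression matrix given")
            expr = pio.load_expression(cfg.expression)
        if cfg.metadata is not None:
            meta = pio.load_metadata(cfg.metadata)
            allowed = set(cfg.allowed_groups) if cfg.allowed_groups else None
            expr = pio.filter_subjects(expr, meta, cfg.min_rin, allowed)
        expr = pio.drop_zero_variance(expr)
    except Exception as exc:
        raise PipelineError(f"input stage: {exc}") from exc

    try:
        net = correlation_network(expr)
    except Exception as exc:
        raise PipelineError(f"network stage: {exc}") from exc

    try:
        topo = topology_profile(net, grid)
        peaks = [
            max(topo, key=lambda s: getattr(s, prop)).threshold
            for prop in ("mean_betweenness", "diameter", "mean_eccentricity")
        ]
        window = (min(peaks), max(peaks))
    except Exception as exc:
        raise PipelineError(f"topology stage: {exc}") from exc

    try:
        max_size = max(cfg.min_size, int(cfg.max_size_frac * net.n_genes))
        records = pmi_scan(
            net, grid, cfg.methods, cfg.target, cfg.min_size,
            seed=det_seed, scope=cfg.scope,
            expr=expr if cfg.n_boot > 0 else None, n_boot=cfg.n_boot,
            max_size=max_size,
        )
        try:
            best_t = select_best_threshold(records, cfg.methods, window=window)
        except ValueError:
            log.warning(
                "no fully valid threshold in the optimal range %s; "
                "falling back to the whole grid", window,
            )
            best_t = select_best_threshold(records, cfg.methods)
    except Exception as exc:
        raise PipelineError(f"PMI stage: {exc}") from exc

    trend = None
    try:
        profile = _average_profile(records, cfg.methods)
        if len(profile) >= 3:
            trend = pmi_trend_test(profile, best_t=best_t)
    except Exception as exc:  # trend fit is advisory; do not abort the run
        log.warning("trend fit skipped: %s", exc)

    try:
        ent = entropy_scan(net, grid, cfg.target, cfg.reference_method, seed=det_seed)
        in_window = [r for r in ent if window[0] - 1e-9 <= r.threshold <= window[1] + 1e-9]
        ent_argmax = max(
            in_window or ent, key=lambda r: r.h_network_per_node
        ).threshold
    except Exception as exc:
        raise PipelineError(f"entropy stage: {exc}") from exc

    step = cfg.grid_step
    confirms = abs(ent_argmax - best_t) <= step * 1.0001
    if not confirms:
        log.warning(
            "entropy argmax %.3f does not confirm PMI threshold %.3f; keeping PMI",
            ent_argmax, best_t,
        )

    try:
        conc = method_concordance(
            net, best_t, cfg.methods, cfg.target, seed=det_seed,
            reference=cfg.reference_method,
            expr=expr if cfg.n_boot > 0 else None, n_boot=cfg.n_boot,
        )
        community = next(
            r.members for r in conc if r.method == cfg.reference_method
        )
    except Exception as exc:
        raise PipelineError(f"concordance stage: {exc}") from exc

    try:
        dice_profile = dice_scan(
            net, best_t, grid, cfg.reference_method, cfg.target,
            seed=det_seed, min_size=cfg.min_size,
        )
    except Exception as exc:
        raise PipelineError(f"stability stage: {exc}") from exc

    try:
        s_net = target_strength_per_node(net, net.gene_ids, cfg.target)
        s_comm = target_strength_per_node(net, community, cfg.target)
        null_mean, null_sd, samples = random_community_null(
            net, cfg.target, size=len(community), n_reps=cfg.null_reps, seed=null_seed
        )
        strengths = StrengthReport(
            strength_per_node_network=s_net,
            strength_per_node_community=s_comm,
            null_mean=null_mean,
            null_sd=null_sd,
            n_null=len(samples),
        )
        hubs = hub_table(net, cfg.hub_cutoff)
        overlap = hub_overlap(hubs, community)
    except Exception as exc:
        raise PipelineError(f"embeddedness stage: {exc}") from exc

    report = PipelineReport(
        config=cfg, topology=topo, pmi_records=records, trend=trend,
        entropy=ent, best_threshold=best_t, optimal_range=window,
        entropy_argmax=ent_argmax,
        entropy_confirms=confirms, community=community, concordance=conc,
        dice_profile=dice_profile, strengths=strengths, hubs=hubs,
        hub_overlap_fraction=overlap, network=net,
    )
    if cfg.out_dir is not None:
        write_report(report, cfg.out_dir)
    return report


def _average_profile(
    records: Sequence[PMIRecord], methods: Sequence[str]
) -> list[tuple[float, float, float]]:
    """Per-threshold cross-method mean PMI with an error estimate.

    The error is the mean bootstrap half-band across methods; where no band
    is available the cross-method standard deviation stands in.
    """
    by_t: dict[float, list[PMIRecord]] = {}
    for r in records:
        if r.valid:
            by_t.setdefault(r.threshold, []).append(r)
    out = []
    for t in sorted(by_t):
        rs = by_t[t]
        if len(rs) < len(methods):
            continue
        mean = float(np.mean([r.pmi for r in rs]))
        bands = [(r.q75 - r.q25) / 2 for r in rs if r.q25 is not None and r.q75 is not None]
        if bands:
            err = float(np.mean(bands))
        else:
            err = float(np.std([r.pmi for r in rs]))
        out.append((t, mean, max(err, 1e-12)))
    return out


def _fmt(x: object) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        return repr(x)
    return str(x)


def _write_tsv(path: Path, header: list[str], rows: list[list[object]]) -> None:
    with path.open("w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def write_report(report: PipelineReport, out_dir: str | Path) -> None:
    """Write all result tables as TSV plus a machine-readable summary.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    _write_tsv(
        out / "topology.tsv",
        ["threshold", "mean_degree", "mean_betweenness", "diameter",
         "mean_eccentricity", "n_nodes", "n_edges"],
        [[s.threshold, s.mean_degree, s.mean_betweenness, s.diameter,
          s.mean_eccentricity, s.n_nodes, s.n_edges] for s in report.topology],
    )
    _write_tsv(
        out / "pmi.tsv",
        ["threshold", "method", "pmi", "size", "q25", "q75"],
        [[r.threshold, r.method, r.pmi, r.size, r.q25, r.q75]
         for r in report.pmi_records],
    )
    _write_tsv(
        out / "entropy.tsv",
        ["threshold", "h_network_per_node", "h_community_per_node",
         "n_network", "n_community"],
        [[r.threshold, r.h_network_per_node, r.h_community_per_node,
          r.n_network, r.n_community] for r in report.entropy],
    )
    _write_tsv(
        out / "dice.tsv",
        ["threshold", "dice", "size"],
        [[r.threshold, r.dice, r.size] for r in report.dice_profile],
    )
    _write_tsv(
        out / "concordance.tsv",
        ["method", "size", "size_q25", "size_q75", "dice_vs_reference"],
        [[r.method, r.size, r.size_q25, r.size_q75, r.dice_vs_reference]
         for r in report.concordance],
    )
    _write_tsv(
        out / "hubs.tsv",
        ["gene", "strength", "scaled_strength"],
        [list(row) for row in report.hubs.rows],
    )
    pio.write_gene_set(sorted(report.community), out / "community.txt")

    summary = {
        "target": report.config.target,
        "best_threshold": report.best_threshold,
        "optimal_range": list(report.optimal_range),
        "entropy_argmax": report.entropy_argmax,
        "entropy_confirms": report.entropy_confirms,
        "community_size": len(report.community),
        "community": sorted(report.community),
        "strength_per_node": {
            "network": report.strengths.strength_per_node_network,
            "community": report.strengths.strength_per_node_community,
            "null_mean": report.strengths.null_mean,
            "null_sd": report.strengths.null_sd,
            "n_null": report.strengths.n_null,
        },
        "hub_overlap": report.hub_overlap_fraction,
        "n_hubs": len(report.hubs.rows),
        "trend": None if report.trend is None else {
            "slope": report.trend.slope,
            "intercept": report.trend.intercept,
            "chi2_reduced": report.trend.chi2_reduced,
            "flagged_thresholds": list(report.trend.flagged),
            "excess_at_best": report.trend.excess_at_best,
        },
        "seed": report.config.seed,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
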