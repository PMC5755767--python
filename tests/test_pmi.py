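"""Pivotal Module Index, bootstrap bands, threshold selection, trend test."""

import itertools

import numpy as np
import pytest

from pivotalnet import (
    ExpressionMatrix,
    PMIRecord,
    PMIUndefinedError,
    TargetCommunity,
    bootstrap_pmi,
    generate,
    correlation_network,
    hard_threshold,
    pmi,
    pmi_scan,
    pmi_trend_test,
    select_best_threshold,
)

from oracle_utils import make_graph, wls_closed_form


def _community(g, members):
    return TargetCommunity(target_gene=sorted(members)[0],
                          members=frozenset(members), threshold=g.threshold,
                          method="fast_greedy")


class TestPmiValue:
    def test_clique_community_scores_zero(self):
        names = [f"v{i}" for i in range(5)]
        g = make_graph(names, list(itertools.combinations(names, 2)))
        assert pmi(g, _community(g, names)) == 0.0

    def test_path_of_three_hand_value(self):
        names = ["a", "b", "c"]
        g = make_graph(names, [("a", "b"), ("b", "c")])
        # mean degree 4/3, mean betweenness 1/3, diameter 2, size 3
        assert pmi(g, _community(g, names)) == pytest.approx(2 / 27)

    def test_star_of_four_hand_value(self):
        names = ["hub", "l1", "l2", "l3"]
        g = make_graph(names, [("hub", leaf) for leaf in names[1:]])
        # mean degree 1.5, mean betweenness 0.75, diameter 2, size 4
        assert pmi(g, _community(g, names)) == pytest.approx(0.140625)

    def test_relabeling_leaves_pmi_unchanged(self):
        names = ["a", "b", "c", "d"]
        g = make_graph(names, [("a", "b"), ("b", "c"), ("c", "d"), ("a", "c")])
        value = pmi(g, _community(g, names))
        renamed = make_graph(["w", "x", "y", "z"],
                             [("w", "x"), ("x", "y"), ("y", "z"), ("w", "y")])
        assert pmi(renamed, _community(renamed, ["w", "x", "y", "z"])) == pytest.approx(value)

    def test_degenerate_communities_raise(self):
        g = make_graph(["a", "b", "c"], [("a", "b")])
        with pytest.raises(PMIUndefinedError):
            pmi(g, _community(g, ["a"]))  # single node
        with pytest.raises(PMIUndefinedError):
            pmi(g, _community(g, ["a", "c"]))  # no internal edge

    def test_global_scope_uses_whole_network_properties(self):
        # path a-b-c-d: community {b, c} induced is a bare edge (PMI 0 via
        # betweenness) but in the whole graph b and c carry the traffic
        names = ["a", "b", "c", "d"]
        g = make_graph(names, [("a", "b"), ("b", "c"), ("c", "d")])
        induced = pmi(g, _community(g, ["b", "c"]), scope="induced")
        whole = pmi(g, _community(g, ["b", "c"]), scope="global")
        assert induced == 0.0
        assert whole == pytest.approx((2.0 * 2.0) / (1 * 2))


class TestScan:
    def test_single_threshold_grid(self, small_network):
        records = pmi_scan(small_network, [0.45], target="DRD2", seed=1)
        assert len(records) == 4
        assert {r.method for r in records} == {"fast_greedy", "louvain", "walktrap", "infomap"}

    def test_empty_edge_threshold_is_flagged_not_fatal(self, small_network):
        t = min(1.0, float(small_network.sim.max()) + 1e-9)
        records = pmi_scan(small_network, [t], target="DRD2", seed=1)
        assert all(not r.valid for r in records)

    def test_min_and_max_size_flagging(self, small_network):
        records = pmi_scan(small_network, [0.0], target="DRD2", seed=1,
                           max_size=small_network.n_genes - 1)
        # at t=0 the whole network is one community: over the size cap
        assert all(not r.valid for r in records)

    def test_argmax_adjacent_to_planted_level(self, small_design):
        matrix, core = generate(small_design)
        net = correlation_network(matrix)
        grid = [round(0.30 + 0.05 * k, 2) for k in range(7)]
        records = pmi_scan(net, grid, target=small_design.target_name, seed=1,
                           max_size=net.n_genes // 2)
        mid = (small_design.r_module + small_design.r_core) / 2
        by_t = {}
        for r in records:
            if r.valid:
                by_t.setdefault(r.threshold, []).append(r.pmi)
        full = {t: np.mean(v) for t, v in by_t.items() if len(v) == 4}
        best = max(sorted(full), key=lambda t: full[t])
        assert abs(best - mid) <= 0.051 * 2  # within two grid steps of the separation level


class TestBootstrap:
    def test_deterministic_given_seed(self, small_planted):
        matrix, _ = small_planted
        a = bootstrap_pmi(matrix, 0.45, "walktrap", "DRD2", n_boot=20, seed=77)
        b = bootstrap_pmi(matrix, 0.45, "walktrap", "DRD2", n_boot=20, seed=77)
        assert a.q25 == b.q25 and a.q75 == b.q75

    def test_quantiles_are_ordered(self, small_planted):
        matrix, _ = small_planted
        s = bootstrap_pmi(matrix, 0.45, "fast_greedy", "DRD2", n_boot=30, seed=5)
        assert s.q25 <= s.median <= s.q75

    def test_requires_at_least_two_replicates(self, small_planted):
        matrix, _ = small_planted
        with pytest.raises(ValueError):
            bootstrap_pmi(matrix, 0.45, "fast_greedy", "DRD2", n_boot=1, seed=0)


class TestSelect:
    def _rec(self, t, method, value, size=10):
        return PMIRecord(threshold=t, method=method, pmi=value, size=size)

    def test_argmax_with_tie_toward_lower_threshold(self):
        methods = ("fast_greedy", "louvain")
        records = [self._rec(t, m, v)
                   for t, v in [(0.4, 1.0), (0.5, 1.0), (0.45, 0.5)]
                   for m in methods]
        assert select_best_threshold(records, methods) == 0.4

    def test_thresholds_missing_a_method_do_not_compete(self):
        methods = ("fast_greedy", "louvain")
        records = [
            self._rec(0.4, "fast_greedy", 9.0),
            PMIRecord(threshold=0.4, method="louvain", pmi=None, size=1),
            self._rec(0.5, "fast_greedy", 1.0),
            self._rec(0.5, "louvain", 1.0),
        ]
        assert select_best_threshold(records, methods) == 0.5

    def test_window_restricts_candidates(self):
        methods = ("fast_greedy",)
        records = [self._rec(t, "fast_greedy", v)
                   for t, v in [(0.3, 5.0), (0.45, 2.0), (0.5, 1.0)]]
        assert select_best_threshold(records, methods) == 0.3
        assert select_best_threshold(records, methods, window=(0.4, 0.55)) == 0.45

    def test_no_valid_threshold_errors(self):
        records = [PMIRecord(0.4, "fast_greedy", None, 1)]
        with pytest.raises(ValueError):
            select_best_threshold(records, ("fast_greedy",))


class TestTrend:
    def test_collinear_points_fit_exactly(self):
        pts = [(t, 2.0 + 3.0 * t, 0.1) for t in (0.3, 0.4, 0.5, 0.6)]
        fit = pmi_trend_test(pts)
        assert fit.slope == pytest.approx(3.0)
        assert fit.intercept == pytest.approx(2.0)
        assert fit.chi2_reduced == pytest.approx(0.0, abs=1e-12)
        assert fit.flagged == ()

    def test_inflated_point_is_flagged(self):
        sigma = 0.01
        pts = [(t, 1.0 + 0.5 * t, sigma) for t in np.linspace(0.3, 0.6, 10)]
        t_hot = 0.45
        pts.append((t_hot, 1.0 + 0.5 * t_hot + 5 * sigma, sigma))
        fit = pmi_trend_test(pts, best_t=t_hot)
        assert t_hot in fit.flagged
        assert fit.excess_at_best

    def test_parameters_match_normal_equations_oracle(self):
        t = np.array([0.30, 0.40, 0.50, 0.60])
        y = np.array([0.8, 1.4, 1.1, 2.0])
        err = np.array([0.1, 0.2, 0.15, 0.3])
        fit = pmi_trend_test(list(zip(t, y, err)))
        intercept, slope = wls_closed_form(t, y, err)
        assert fit.intercept == pytest.approx(intercept)
        assert fit.slope == pytest.approx(slope)

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            pmi_trend_test([(0.3, 1.0, 0.1), (0.4, 1.2, 0.1)])
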