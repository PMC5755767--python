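"""Community detection contracts and modularity."""

import itertools

import numpy as np
import pytest

from pivotalnet import (
    METHODS,
    Partition,
    detect_communities,
    dice,
    generate,
    hard_threshold,
    correlation_network,
    modularity,
    target_community,
)

from oracle_utils import make_graph, modularity_oracle, set_partitions


def _two_cliques(k):
    """Two K_k cliques joined by a single bridge edge."""
    left = [f"a{i}" for i in range(k)]
    right = [f"b{i}" for i in range(k)]
    edges = list(itertools.combinations(left, 2)) + list(itertools.combinations(right, 2))
    edges.append((left[0], right[0]))
    return make_graph(left + right, edges), left, right


class TestModularity:
    def test_single_community_is_zero(self):
        g, left, right = _two_cliques(4)
        p = Partition("fast_greedy", {v: 0 for v in g.gene_ids}, 0.5, 0)
        assert modularity(g, p) == pytest.approx(0.0)

    def test_two_triangles_hand_value(self):
        g, left, right = _two_cliques(3)
        labels = {v: 0 for v in left} | {v: 1 for v in right}
        p = Partition("fast_greedy", labels, 0.5, 0)
        assert modularity(g, p) == pytest.approx(5 / 14)  # 2*(3/7 - (7/14)^2)

    def test_singleton_partition_is_negative(self):
        g, *_ = _two_cliques(3)
        p = Partition("fast_greedy", {v: i for i, v in enumerate(g.gene_ids)}, 0.5, 0)
        deg = g.adj.sum(axis=1)
        expected = -np.sum((deg / (2 * g.n_edges)) ** 2)
        assert modularity(g, p) == pytest.approx(expected)
        assert modularity(g, p) < 0

    def test_edgeless_graph_errors(self):
        g = make_graph(["a", "b", "c"], [])
        p = Partition("fast_greedy", {"a": 0, "b": 1, "c": 2}, 0.5, 0)
        with pytest.raises(ValueError):
            modularity(g, p)

    def test_matches_pair_sum_oracle_on_random_partitions(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            n = int(rng.integers(4, 9))
            adj = rng.random((n, n)) < 0.5
            adj = np.triu(adj, 1)
            adj = adj | adj.T
            if adj.sum() == 0:
                continue
            names = [f"v{i}" for i in range(n)]
            g = make_graph(names, [(names[i], names[j])
                                   for i, j in zip(*np.nonzero(np.triu(adj, 1)))])
            labels = rng.integers(0, 3, size=n)
            p = Partition("fast_greedy", dict(zip(names, labels.tolist())), 0.5, 0)
            assert modularity(g, p) == pytest.approx(modularity_oracle(adj, labels))


class TestDetection:
    def test_two_k5_cliques_split_by_every_method(self):
        g, left, right = _two_cliques(5)
        for method in METHODS:
            p = detect_communities(g, method, seed=4)
            comms = {frozenset(c) for c in p.communities()}
            assert comms == {frozenset(left), frozenset(right)}, method

    def test_clique_split_is_the_exhaustive_modularity_optimum(self):
        # brute force over every partition of the 10 nodes confirms that the
        # two cliques are the best-possible split, so modularity optimizers
        # returning it is correct, not conventional
        g, left, right = _two_cliques(5)
        target_labels = {v: 0 for v in left} | {v: 1 for v in right}
        q_cliques = modularity(g, Partition("fast_greedy", target_labels, 0.5, 0))
        best = -np.inf
        index = {v: i for i, v in enumerate(g.gene_ids)}
        labels = np.empty(g.n_nodes, dtype=int)
        for part in set_partitions(g.gene_ids):
            for i, block in enumerate(part):
                for v in block:
                    labels[index[v]] = i
            best = max(best, modularity_oracle(g.adj, labels))
        assert q_cliques == pytest.approx(best)

    def test_single_clique_is_one_community(self):
        names = [f"v{i}" for i in range(6)]
        g = make_graph(names, list(itertools.combinations(names, 2)))
        for method in METHODS:
            assert len(detect_communities(g, method, seed=0).communities()) == 1

    def test_determinism_per_seed(self, small_network):
        g = hard_threshold(small_network, 0.45)
        for method in METHODS:
            p1 = detect_communities(g, method, seed=123)
            p2 = detect_communities(g, method, seed=123)
            assert p1.labels == p2.labels

    def test_isolated_nodes_become_singletons(self):
        g = make_graph(["a", "b", "c", "d"], [("a", "b")])
        for method in METHODS:
            p = detect_communities(g, method, seed=0)
            assert p.labels["c"] != p.labels["d"]
            assert {p.labels["c"]} != {p.labels["a"], p.labels["b"]}

    def test_unknown_method_errors(self):
        g = make_graph(["a", "b", "c"], [("a", "b")])
        with pytest.raises(ValueError):
            detect_communities(g, "leiden", seed=0)

    def test_labels_are_contiguous_cover(self, small_network):
        g = hard_threshold(small_network, 0.5)
        for method in METHODS:
            p = detect_communities(g, method, seed=9)
            assert set(p.labels) == set(g.gene_ids)
            ids = set(p.labels.values())
            assert ids == set(range(len(ids)))


class TestTargetCommunity:
    def test_singleton_target(self):
        g = make_graph(["a", "b", "c"], [("a", "b")])
        p = detect_communities(g, "fast_greedy", seed=0)
        assert target_community(p, "c").members == frozenset({"c"})

    def test_label_permutation_leaves_members_unchanged(self):
        g, left, right = _two_cliques(4)
        p = detect_communities(g, "walktrap", seed=0)
        remap = {0: 7, 1: 3}
        q = Partition(p.method, {g_: remap.get(c, c) for g_, c in p.labels.items()},
                      p.threshold, p.seed)
        assert target_community(p, "a0").members == target_community(q, "a0").members

    def test_absent_target_errors(self):
        g = make_graph(["a", "b", "c"], [("a", "b")])
        p = detect_communities(g, "fast_greedy", seed=0)
        with pytest.raises(KeyError):
            target_community(p, "zzz")

    def test_planted_core_recovered_at_separating_threshold(self, small_design):
        matrix, core = generate(small_design)
        net = correlation_network(matrix)
        mid = (small_design.r_module + small_design.r_core) / 2
        g = hard_threshold(net, mid)
        for method in METHODS:
            comm = target_community(
                detect_communities(g, method, seed=2), small_design.target_name
            )
            assert dice(comm.members, core) >= 0.8, method
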