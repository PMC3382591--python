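"""Minimal connected network extraction, node metrics and significance."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from _oracles import brute_force_betweenness, brute_force_clustering
from tfnet.errors import ConfigError, PreconditionError
from tfnet.mcn import (PpiNetwork, betweenness, central_nodes,
                       clustering_coefficient, minimal_connected_network,
                       negative_control, subnetwork_significance)


class TestMinimalConnectedNetwork:
    def test_direct_edge_pair(self):
        g = nx.Graph([("a", "b"), ("b", "x")])
        res = minimal_connected_network({"a", "b"}, g)
        assert set(res.mcn.edges) == {("a", "b")}

    def test_single_intermediate_path(self):
        g = nx.Graph([("a", "w"), ("w", "c"), ("x", "y")])
        res = minimal_connected_network({"a", "c"}, g)
        assert set(res.mcn.nodes) == {"a", "w", "c"}
        assert res.node_metrics.loc["w", "is_seed"] == False  # noqa: E712

    def test_distance_three_seeds_unconnected(self):
        g = nx.path_graph(["a", "x", "y", "d"])
        res = minimal_connected_network({"a", "d"}, g)
        assert res.subnetwork.number_of_edges() == 0
        assert res.mcn.number_of_nodes() == 0

    def test_direct_edge_does_not_pull_in_common_neighbors(self):
        """A seed pair at distance 1 contributes only its direct edge."""
        g = nx.Graph([("a", "b"), ("a", "w"), ("w", "b")])
        res = minimal_connected_network({"a", "b"}, g)
        assert set(res.mcn.nodes) == {"a", "b"}

    def test_all_common_neighbors_included(self):
        g = nx.Graph([("a", "w1"), ("w1", "b"), ("a", "w2"), ("w2", "b")])
        res = minimal_connected_network({"a", "b"}, g)
        assert set(res.mcn.nodes) == {"a", "b", "w1", "w2"}

    def test_largest_component_by_edges_and_discard_small(self):
        # component 1: 3 seeds in a triangle (3 edges); component 2: pair (1 edge)
        g = nx.Graph([("s1", "s2"), ("s2", "s3"), ("s1", "s3"), ("s4", "s5")])
        res = minimal_connected_network({"s1", "s2", "s3", "s4", "s5"}, g)
        assert set(res.mcn.nodes) == {"s1", "s2", "s3"}
        assert len(res.components) == 2

    def test_unmapped_seeds_reported(self):
        g = nx.Graph([("a", "b")])
        res = minimal_connected_network({"a", "b", "ghost"}, g)
        assert res.unmapped_seeds == {"ghost"}
        with pytest.raises(PreconditionError):
            minimal_connected_network({"a", "ghost"}, g)

    def test_relabeling_invariance(self, rng):
        g = nx.gnp_random_graph(15, 0.25, seed=42)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g})
        seeds = {"n0", "n3", "n7", "n11"}
        res = minimal_connected_network(seeds, g)
        mapping = {n: f"z{n}" for n in g}
        res2 = minimal_connected_network({mapping[s] for s in seeds},
                                         nx.relabel_nodes(g, mapping))
        assert {mapping[n] for n in res.mcn.nodes} == set(res2.mcn.nodes)
        assert nx.is_isomorphic(res.mcn, res2.mcn)

    def test_subnetwork_edges_match_independent_reconstruction(self, rng):
        """The subnetwork equals the edge set rebuilt from first
        principles: direct seed-seed edges plus, for non-adjacent seed
        pairs sharing a neighbor, both edges through each common
        neighbor."""
        for trial in range(20):
            g = nx.gnp_random_graph(12, 0.25, seed=100 + trial)
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g})
            seeds = {f"n{i}" for i in rng.choice(12, size=4, replace=False)}
            try:
                res = minimal_connected_network(seeds, g)
            except PreconditionError:
                continue
            expected = set()
            for s, t in itertools.combinations(sorted(seeds), 2):
                if g.has_edge(s, t):
                    expected.add(frozenset((s, t)))
                else:
                    for w in set(g[s]) & set(g[t]):
                        expected.add(frozenset((s, w)))
                        expected.add(frozenset((t, w)))
            got = {frozenset(e) for e in res.subnetwork.edges}
            assert got == expected


class TestNodeMetrics:
    def test_path_betweenness(self):
        g = nx.path_graph(["a", "b", "c"])
        assert betweenness(g) == {"a": 0.0, "b": 1.0, "c": 0.0}

    def test_star_center_betweenness(self):
        g = nx.star_graph(4)  # center 0, leaves 1..4
        assert betweenness(g)[0] == pytest.approx(6.0)  # C(4,2)

    def test_triangle_and_star_clustering(self):
        tri = nx.complete_graph(3)
        assert clustering_coefficient(tri, 0) == 1.0
        star = nx.star_graph(4)
        assert clustering_coefficient(star, 0) == 0.0

    def test_one_edge_among_three_neighbors(self):
        g = nx.Graph([("n", "x"), ("n", "y"), ("n", "z"), ("x", "y")])
        assert clustering_coefficient(g, "n") == pytest.approx(1 / 3)

    def test_tree_betweenness_sum_identity(self):
        """On a tree, summed pair dependencies equal sum over edges of
        n1*n2 minus the number of pairs (interior credit identity)."""
        t = nx.random_labeled_tree(12, seed=7)
        btw = betweenness(t)
        n = t.number_of_nodes()
        edge_sum = 0
        for a, b in t.edges:
            t.remove_edge(a, b)
            comp = nx.node_connected_component(t, a)
            edge_sum += len(comp) * (n - len(comp))
            t.add_edge(a, b)
        assert sum(btw.values()) == pytest.approx(edge_sum - n * (n - 1) / 2)

    def test_matches_brute_force_on_random_graphs(self, rng):
        for trial in range(10):
            g = nx.gnp_random_graph(9, 0.3, seed=300 + trial)
            btw = betweenness(g)
            oracle = brute_force_betweenness(g)
            for node in g:
                assert btw[node] == pytest.approx(oracle[node], abs=1e-9)
                assert clustering_coefficient(g, node) == pytest.approx(
                    brute_force_clustering(g, node), abs=1e-12)


class TestSignificanceAndControl:
    def _module_graph(self, seed=0):
        """Sparse background plus a planted hub-bridged seed module: the
        seeds reach each other through a few heavily wired hub proteins,
        so the extracted MCN is dense and hub-centred."""
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(120, 0.015, seed=seed)
        g = nx.relabel_nodes(g, {i: f"p{i:03d}" for i in g})
        seeds = [f"p{i:03d}" for i in range(15)]
        hubs = [f"p{i:03d}" for i in range(115, 119)]
        for s in seeds:
            for h in hubs:
                if rng.random() < 0.55:
                    g.add_edge(s, h)
        for a, b in itertools.combinations(hubs, 2):
            g.add_edge(a, b)
        return g, seeds

    def test_nonpositive_n_random_rejected(self):
        g, seeds = self._module_graph()
        res = minimal_connected_network(seeds, g)
        with pytest.raises(ConfigError):
            subnetwork_significance(res, g, n_random=0)

    def test_planted_module_density_is_significant(self):
        """The hub-bridged seed module is far denser than random-set
        MCNs: the degree and clustering KS tests both flag it."""
        g, seeds = self._module_graph()
        res = minimal_connected_network(seeds, g)
        pvals = subnetwork_significance(res, g, n_random=150, rng_seed=5)
        assert pvals["connections"] <= 0.01
        assert pvals["betweenness"] <= 0.05

    def test_full_scale_planted_module_flags_all_metrics(self):
        """At the default study scale (bridge-layer module over 38 driver
        seeds) all three KS tests are strongly significant and the
        random-TF-list negative control separates the planted seeds."""
        from tfnet.synthetic import (SyntheticConfig, generate_catalogue,
                                     generate_cell_line_data, generate_ppi)
        cfg = SyntheticConfig(rng_seed=7)
        cat = generate_catalogue(cfg)
        _, _, _, truth = generate_cell_line_data(cat, cfg)
        graph = PpiNetwork.from_frame(generate_ppi(truth, cfg)).filtered(2)
        seeds = sorted(t for t in truth.driver_tfs if t in graph)
        res = minimal_connected_network(seeds, graph)
        pvals = subnetwork_significance(res, graph, n_random=150, rng_seed=5)
        assert all(p <= 0.01 for p in pvals.values())
        p = negative_control(sorted(cat.tfs), graph, res,
                             list_size=len(seeds), n_lists=40, rng_seed=3)
        assert p <= 0.05

    def test_significance_reproducible_under_seed(self):
        g, seeds = self._module_graph()
        res = minimal_connected_network(seeds, g)
        a = subnetwork_significance(res, g, n_random=80, rng_seed=11)
        b = subnetwork_significance(res, g, n_random=80, rng_seed=11)
        assert a == b

    def test_negative_control_identical_lists_ks_null(self):
        """With the observed seed list itself as the only random list,
        the two betweenness samples coincide and KS cannot reject."""
        g, seeds = self._module_graph()
        res = minimal_connected_network(seeds, g)
        p = negative_control(seeds, g, res, list_size=len(seeds),
                             n_lists=1, rng_seed=0)
        assert p > 0.9

    def test_list_size_larger_than_universe_rejected(self):
        g, seeds = self._module_graph()
        res = minimal_connected_network(seeds, g)
        with pytest.raises(PreconditionError):
            negative_control(["a", "b"], g, res, list_size=5)


class TestCentralNodes:
    def _metrics(self, btw, deg=None):
        idx = [f"n{i}" for i in range(len(btw))]
        return pd.DataFrame({"betweenness": btw,
                             "connections": deg or [1] * len(btw),
                             "clustering": 0.0}, index=idx)

    def test_all_equal_scores_gives_empty_above_average(self):
        cn = central_nodes(self._metrics([2.0, 2.0, 2.0]), k=2)
        assert cn.above_average == frozenset()

    def test_tie_broken_by_degree_then_id(self):
        cn = central_nodes(self._metrics([10.0, 1.0, 1.0], deg=[3, 1, 2]), k=2)
        assert cn.above_average == frozenset({"n0"})
        assert cn.top == ["n0", "n2"]  # n2 beats n1 on degree

    def test_top_share_fraction(self):
        cn = central_nodes(self._metrics([6.0, 3.0, 1.0]), k=2)
        assert cn.top_share == pytest.approx(0.9)

    def test_k_clamped_to_size(self):
        cn = central_nodes(self._metrics([1.0, 2.0]), k=10)
        assert len(cn.top) == 2
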