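"""Modularity and move-gain correctness against dense full-recompute oracles."""

import numpy as np
import pytest

from dirleiden import (CSRGraph, Membership, build_directed_view,
                       delta_q_directed, delta_q_undirected,
                       directed_aggregates, modularity_directed,
                       modularity_undirected, node_links_directed,
                       node_links_undirected, undirected_aggregates)

from conftest import (dense_modularity_directed, dense_modularity_undirected,
                      random_graph)


# ---------------------------------------------------------------------------
# helpers: net move gain via the public incremental API
# ---------------------------------------------------------------------------

def net_gain_undirected(g, p, i, target, gamma=1.0):
    """Gain of moving node i to ``target`` computed incrementally."""
    agg = undirected_aggregates(g, p)
    links = node_links_undirected(g, p, i)
    k_i = float(g.strength[i])
    home = int(p.assign[i])
    # detach i from its community
    agg.sigma_tot[home] -= k_i
    agg.sigma_in[home] -= 2.0 * links.get(home, 0.0) + 2.0 * float(g.self_loop[i])
    back = delta_q_undirected(agg, links, k_i, home, gamma, g.m)
    into = delta_q_undirected(agg, links, k_i, target, gamma, g.m)
    return into - back


def net_gain_directed(view, p, i, target, gamma=1.0):
    g = view.out_csr
    agg = directed_aggregates(g, p)
    links = node_links_directed(view, p, i)
    k_out = float(g.out_strength[i])
    k_in = float(g.in_strength[i])
    home = int(p.assign[i])
    agg.s_out[home] -= k_out
    agg.s_in[home] -= k_in
    agg.sigma_in[home] -= (links[0].get(home, 0.0) + links[1].get(home, 0.0)
                           + float(g.self_loop[i]))
    back = delta_q_directed(agg, links, k_out, k_in, home, gamma, g.m)
    into = delta_q_directed(agg, links, k_out, k_in, target, gamma, g.m)
    return into - back


def moved(p, i, target):
    a = p.assign.copy()
    a[i] = target
    return Membership(a, max(p.n_communities, target + 1))


# ---------------------------------------------------------------------------
# modularity values
# ---------------------------------------------------------------------------

class TestModularityUndirected:
    def test_all_in_one_community_is_zero(self):
        rng = np.random.default_rng(0)
        g = random_graph(rng, 10, 30, directed=False, loops=True)
        p = Membership(np.zeros(10, dtype=np.int64), 1)
        assert modularity_undirected(g, p) == pytest.approx(0.0, abs=1e-14)

    def test_two_disjoint_triangles(self):
        g = CSRGraph.from_edges(6, [0, 1, 2, 3, 4, 5],
                                [1, 2, 0, 4, 5, 3], directed=False)
        p = Membership(np.array([0, 0, 0, 1, 1, 1]))
        assert modularity_undirected(g, p) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_dense_double_sum(self, seed):
        rng = np.random.default_rng(seed)
        g = random_graph(rng, 12, 40, directed=False, loops=True)
        p = Membership.from_labels(rng.integers(0, 4, 12))
        gamma = float(rng.uniform(0.5, 2.0))
        assert modularity_undirected(g, p, gamma) == pytest.approx(
            dense_modularity_undirected(g, p, gamma), abs=1e-12)

    def test_rejects_directed(self):
        g = CSRGraph.from_edges(2, [0], [1], directed=True)
        with pytest.raises(ValueError):
            modularity_undirected(g, Membership.singletons(2))

    def test_relabeling_invariance_and_bound(self):
        rng = np.random.default_rng(11)
        g = random_graph(rng, 15, 50, directed=False)
        labels = rng.integers(0, 5, 15)
        q1 = modularity_undirected(g, Membership.from_labels(labels))
        perm = rng.permutation(5)
        q2 = modularity_undirected(g, Membership.from_labels(perm[labels]))
        assert q1 == pytest.approx(q2, abs=1e-14)
        assert q1 <= 1.0


class TestModularityDirected:
    def test_all_in_one_community_is_zero(self):
        rng = np.random.default_rng(1)
        g = random_graph(rng, 10, 40, directed=True, loops=True)
        p = Membership(np.zeros(10, dtype=np.int64), 1)
        assert modularity_directed(g, p) == pytest.approx(0.0, abs=1e-14)

    def test_two_cycle_singletons(self):
        g = CSRGraph.from_edges(2, [0, 1], [1, 0], directed=True)
        assert modularity_directed(g, Membership.singletons(2)) == \
            pytest.approx(-0.5)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_dense_double_sum(self, seed):
        rng = np.random.default_rng(50 + seed)
        g = random_graph(rng, 12, 45, directed=True, loops=True)
        p = Membership.from_labels(rng.integers(0, 4, 12))
        gamma = float(rng.uniform(0.5, 2.0))
        assert modularity_directed(g, p, gamma) == pytest.approx(
            dense_modularity_directed(g, p, gamma), abs=1e-12)

    def test_mirrored_digraph_equals_undirected(self, mirrored_pair):
        gu, gd = mirrored_pair
        rng = np.random.default_rng(9)
        for _ in range(10):
            p = Membership.from_labels(rng.integers(0, 6, gu.n))
            gamma = float(rng.uniform(0.5, 2.0))
            assert modularity_directed(gd, p, gamma) == pytest.approx(
                modularity_undirected(gu, p, gamma), abs=1e-12)


# ---------------------------------------------------------------------------
# incremental gains: the central correctness oracle
# ---------------------------------------------------------------------------

class TestDeltaQ:
    def test_identity_move_is_zero_undirected(self):
        rng = np.random.default_rng(2)
        g = random_graph(rng, 10, 30, directed=False)
        p = Membership.from_labels(rng.integers(0, 3, 10))
        assert net_gain_undirected(g, p, 4, int(p.assign[4])) == \
            pytest.approx(0.0, abs=1e-14)

    def test_isolated_node_all_gains_zero(self):
        g = CSRGraph.from_edges(4, [0, 1], [1, 0], [1.0, 2.0], directed=False)
        # nodes 2, 3 isolated
        p = Membership.from_labels(np.array([0, 0, 1, 2]))
        for target in range(3):
            assert net_gain_undirected(g, p, 3, target) == \
                pytest.approx(0.0, abs=1e-14)

    @pytest.mark.parametrize("case", range(200))
    def test_undirected_gain_equals_full_recompute(self, case):
        rng = np.random.default_rng(1000 + case)
        n = int(rng.integers(5, 16))
        g = random_graph(rng, n, int(rng.integers(n, 4 * n)),
                         directed=False, loops=bool(case % 3 == 0))
        if g.m == 0:
            return
        p = Membership.from_labels(rng.integers(0, max(2, n // 3), n))
        i = int(rng.integers(0, n))
        target = int(rng.integers(0, p.n_communities))
        gamma = float(rng.uniform(0.5, 2.0))
        inc = net_gain_undirected(g, p, i, target, gamma)
        full = (modularity_undirected(g, moved(p, i, target), gamma)
                - modularity_undirected(g, p, gamma))
        assert inc == pytest.approx(full, abs=1e-12)

    @pytest.mark.parametrize("case", range(200))
    def test_directed_gain_equals_full_recompute(self, case):
        rng = np.random.default_rng(5000 + case)
        n = int(rng.integers(5, 16))
        g = random_graph(rng, n, int(rng.integers(n, 4 * n)),
                         directed=True, loops=bool(case % 3 == 0))
        if g.m == 0:
            return
        view = build_directed_view(g)
        p = Membership.from_labels(rng.integers(0, max(2, n // 3), n))
        i = int(rng.integers(0, n))
        target = int(rng.integers(0, p.n_communities))
        gamma = float(rng.uniform(0.5, 2.0))
        inc = net_gain_directed(view, p, i, target, gamma)
        full = (modularity_directed(g, moved(p, i, target), gamma)
                - modularity_directed(g, p, gamma))
        assert inc == pytest.approx(full, abs=1e-12)

    def test_zero_m_is_contract_error(self):
        g = CSRGraph.from_edges(3, [], [], directed=False)
        p = Membership.singletons(3)
        agg = undirected_aggregates(g, p)
        with pytest.raises(ValueError):
            delta_q_undirected(agg, {}, 0.0, 0, 1.0, 0.0)


class TestAggregatesInvariants:
    def test_sigma_tot_sums_to_two_m(self):
        rng = np.random.default_rng(3)
        g = random_graph(rng, 20, 60, directed=False, loops=True)
        p = Membership.from_labels(rng.integers(0, 5, 20))
        agg = undirected_aggregates(g, p)
        assert agg.sigma_tot.sum() == pytest.approx(2 * g.m)
        assert (agg.sigma_in >= 0).all()

    def test_directed_strength_sums_to_m(self):
        rng = np.random.default_rng(4)
        g = random_graph(rng, 20, 80, directed=True, loops=True)
        p = Membership.from_labels(rng.integers(0, 5, 20))
        agg = directed_aggregates(g, p)
        assert agg.s_out.sum() == pytest.approx(g.m)
        assert agg.s_in.sum() == pytest.approx(g.m)
        assert agg.sigma_in.sum() <= g.m + 1e-12

    def test_node_links_sum_rule(self):
        rng = np.random.default_rng(5)
        g = random_graph(rng, 15, 60, directed=True, loops=True)
        view = build_directed_view(g)
        p = Membership.from_labels(rng.integers(0, 4, 15))
        for i in range(g.n):
            k_out_to, k_in_from = node_links_directed(view, p, i)
            assert sum(k_out_to.values()) == pytest.approx(
                g.out_strength[i] - g.self_loop[i])
            assert sum(k_in_from.values()) == pytest.approx(
                g.in_strength[i] - g.self_loop[i])
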