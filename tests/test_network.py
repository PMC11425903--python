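import itertools

import networkx as nx
import numpy as np
import pytest

from microstab import (
    build_network,
    detect_modules,
    robustness,
    small_world_sigma,
    topology,
    vulnerability,
    zi_pi,
)
from microstab.network import SignedNetwork


def _net(graph):
    for u, v in graph.edges:
        graph[u][v].setdefault("sign", 1)
        graph[u][v].setdefault("weight", 1.0)
    return SignedNetwork(graph=graph)


class TestTopology:
    def test_triangle(self):
        rec = topology(_net(nx.complete_graph(3)))
        assert (rec.n, rec.L) == (3, 3)
        assert rec.avgK == pytest.approx(2.0)
        assert rec.avgCC == pytest.approx(1.0)
        assert rec.GD == pytest.approx(1.0)

    def test_star_is_maximally_centralized(self):
        rec = topology(_net(nx.star_graph(3)))  # hub + 3 leaves
        assert rec.CD == pytest.approx(1.0)

    def test_regular_graph_has_zero_centralization(self):
        rec = topology(_net(nx.cycle_graph(6)))
        assert rec.CD == pytest.approx(0.0)

    def test_avgk_identity_holds_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            g = nx.gnm_random_graph(20, int(rng.integers(19, 60)),
                                    seed=int(rng.integers(1000)))
            g.remove_nodes_from(list(nx.isolates(g)))
            if g.number_of_nodes() < 2:
                continue
            rec = topology(_net(g))
            assert rec.avgK == pytest.approx(2 * rec.L / rec.n)

    def test_single_node_rejected(self):
        g = nx.Graph()
        g.add_node("a")
        with pytest.raises(ValueError):
            topology(_net(g))


class TestSmallWorld:
    def test_erdos_renyi_sigma_near_one(self):
        g = nx.gnm_random_graph(100, 300, seed=4)
        sigma = small_world_sigma(_net(g), n_random=30, seed=0)
        assert sigma == pytest.approx(1.0, abs=0.2)

    def test_watts_strogatz_sigma_above_one(self):
        g = nx.watts_strogatz_graph(100, 6, 0.05, seed=2)
        sigma = small_world_sigma(_net(g), n_random=30, seed=0)
        assert sigma > 1.0

    def test_seed_reproducible(self):
        g = nx.gnm_random_graph(40, 80, seed=1)
        net = _net(g)
        assert small_world_sigma(net, n_random=15, seed=9) == small_world_sigma(
            net, n_random=15, seed=9
        )


class TestModules:
    def test_two_disjoint_triangles(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")])
        g.add_edges_from([("x", "y"), ("y", "z"), ("x", "z")])
        membership = detect_modules(_net(g))
        assert len(set(membership.values())) == 2
        assert membership["a"] == membership["b"] == membership["c"]
        assert membership["x"] == membership["y"] == membership["z"]

    def test_complete_graph_is_one_module(self):
        membership = detect_modules(_net(nx.complete_graph(6)))
        assert len(set(membership.values())) == 1

    def test_planted_blocks_recovered(self, flat_block_cohort):
        from sklearn.metrics import adjusted_rand_score

        from microstab import correlation_matrix, prepare_abundances, rmt_threshold

        _, table, meta, _, truth = flat_block_cohort
        ids, prep = prepare_abundances(table)
        corr = correlation_matrix(ids, prep)
        net = build_network(corr, rmt_threshold(corr).threshold)
        membership = detect_modules(net)
        planted = {
            t: truth.module_membership[int(t.split("_")[1])] for t in membership
        }
        in_modules = [t for t in membership if planted[t] >= 0]
        ari = adjusted_rand_score(
            [planted[t] for t in in_modules], [membership[t] for t in in_modules]
        )
        assert ari >= 0.8


class TestZiPi:
    def test_all_edges_inside_module_gives_zero_pi(self):
        g = nx.complete_graph(4)
        net = _net(g)
        roles = zi_pi(net, {n: 0 for n in g.nodes})
        assert all(r.pi == 0.0 for r in roles)

    def test_even_split_across_two_modules(self):
        g = nx.Graph()
        g.add_edges_from([("hub", x) for x in ["a1", "a2", "b1", "b2"]])
        membership = {"hub": 0, "a1": 0, "a2": 0, "b1": 1, "b2": 1}
        roles = {r.taxon_id: r for r in zi_pi(_net(g), membership)}
        assert roles["hub"].pi == pytest.approx(0.5)

    def test_uniform_within_module_degree_gives_zero_zi(self):
        g = nx.cycle_graph(5)
        roles = zi_pi(_net(g), {n: 0 for n in g.nodes})
        assert all(r.zi == 0.0 for r in roles)
        assert all(r.role == "peripheral" for r in roles)

    def test_zi_invariant_to_module_relabeling(self):
        g = nx.gnm_random_graph(30, 60, seed=3)
        g.remove_nodes_from(list(nx.isolates(g)))
        net = _net(g)
        membership = detect_modules(net)
        relabeled = {n: 100 - m for n, m in membership.items()}
        a = {r.taxon_id: r.zi for r in zi_pi(net, membership)}
        b = {r.taxon_id: r.zi for r in zi_pi(net, relabeled)}
        assert a == b

    def test_pi_stays_below_one(self):
        g = nx.gnm_random_graph(30, 80, seed=6)
        g.remove_nodes_from(list(nx.isolates(g)))
        net = _net(g)
        roles = zi_pi(net, detect_modules(net))
        assert all(0.0 <= r.pi < 1.0 for r in roles)


class TestRobustness:
    def test_complete_graph_fully_robust(self):
        mean, sd = robustness(_net(nx.complete_graph(8)), 0.5, n_rep=20, seed=0)
        assert mean == pytest.approx(1.0)
        assert sd == pytest.approx(0.0)

    def test_perfect_matching_matches_exact_enumeration(self):
        # 3 disjoint edges on 6 nodes, remove 3: enumerate all C(6,3)=20
        g = nx.Graph()
        g.add_edges_from([(0, 1), (2, 3), (4, 5)])
        expected = []
        for removed in itertools.combinations(range(6), 3):
            keep = [n for n in range(6) if n not in removed]
            sub = g.subgraph(keep)
            with_edge = sum(1 for n in keep if sub.degree(n) > 0)
            expected.append(with_edge / len(keep))
        exact = np.mean(expected)
        mean, _ = robustness(_net(g), 0.5, n_rep=4000, seed=1)
        assert mean == pytest.approx(exact, abs=0.02)

    def test_seed_reproducible(self):
        net = _net(nx.gnm_random_graph(20, 40, seed=2))
        assert robustness(net, 0.5, 50, seed=3) == robustness(net, 0.5, 50, seed=3)


class TestVulnerability:
    def test_path_graph_cut_vertex(self):
        # a-b-c: E = (1 + 1 + 1/2)/3; removing b disconnects -> V = 1
        g = nx.path_graph(3)
        assert vulnerability(_net(g)) == pytest.approx(1.0)

    def test_complete_graph_has_zero_vulnerability(self):
        assert vulnerability(_net(nx.complete_graph(4))) == pytest.approx(0.0)

    def test_cycle_symmetry(self):
        g = nx.cycle_graph(4)
        v = vulnerability(_net(g))
        # every node is equivalent; removal leaves P3 with E = 5/6
        e_full = (4 * 1 + 2 * 0.5) / 6
        e_without = (2 * 1 + 0.5) / 3
        assert v == pytest.approx((e_full - e_without) / e_full)

    def test_too_small_rejected(self):
        g = nx.path_graph(2)
        with pytest.raises(ValueError):
            vulnerability(_net(g))
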