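"""Co-occurrence network construction, topology oracles, modules, Zi–Pi."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bentho import CommunityTable, build_network, detect_modules, major_modules, topology_metrics, topology_with_null, zi_pi
from bentho.network import Network, classify_role, _random_gnm_adjacency


def _table_from_matrix(mat):
    return CommunityTable(
        counts=pd.DataFrame(
            mat,
            index=[f"S{i}" for i in range(mat.shape[0])],
            columns=[f"T{j}" for j in range(mat.shape[1])],
        )
    )


def _net_from_graph(g):
    edges = pd.DataFrame(
        [(u, v, 1.0, 0.0, "positive") for u, v in g.edges],
        columns=["source", "target", "rho", "p", "sign"],
    )
    return Network(graph=g, edges=edges, positive_fraction=1.0, negative_fraction=0.0)


class TestBuildNetwork:
    def test_perfect_rank_correlation_edge(self):
        rng = np.random.default_rng(0)
        base = rng.integers(1, 100, size=12)
        mat = np.column_stack([base, base * 2, rng.permutation(base)])
        mat = np.tile(mat, (1, 1))
        table = _table_from_matrix(mat)
        net = build_network(table, min_prevalence=0.01, r_threshold=0.7, p_threshold=0.05)
        g = net.graph
        assert g.has_edge("T0", "T1")
        assert g["T0"]["T1"]["rho"] == pytest.approx(1.0)
        assert g["T0"]["T1"]["sign"] == "positive"

    def test_null_edge_rate_matches_permutation_oracle(self):
        # independent taxa at n=35: the observed edge count over 200 tables
        # should match the per-pair rejection rate of the joint criterion,
        # estimated by brute-force independent-pair simulation
        n, k = 35, 10
        rng = np.random.default_rng(1)
        # brute-force estimate of P(|rho|>0.7 and p<0.05) for independent pairs
        n_pairs_mc = 30_000
        a = rng.permuted(np.tile(np.arange(n, dtype=float), (n_pairs_mc, 1)), axis=1)
        b = rng.permuted(np.tile(np.arange(n, dtype=float), (n_pairs_mc, 1)), axis=1)
        ac = a - a.mean(1, keepdims=True)
        bc = b - b.mean(1, keepdims=True)
        rho = (ac * bc).sum(1) / np.sqrt((ac**2).sum(1) * (bc**2).sum(1))
        t = rho * np.sqrt((n - 2) / (1 - rho**2))
        p = 2 * stats.t.sf(np.abs(t), n - 2)
        p_hit = float(((np.abs(rho) > 0.7) & (p < 0.05)).mean())

        n_rep, pairs = 200, k * (k - 1) // 2
        hits = 0
        for rep in range(n_rep):
            mat = rng.integers(1, 1000, size=(n, k))
            table = _table_from_matrix(mat)
            try:
                net = build_network(table, min_prevalence=0.01)
                hits += net.n_edges
            except ValueError:
                pass
        mean = n_rep * pairs * p_hit
        se = np.sqrt(n_rep * pairs * p_hit * (1 - p_hit))
        assert abs(hits - mean) <= 3 * se + 1

    def test_too_few_taxa_errors(self):
        mat = np.ones((12, 3), dtype=int)
        mat[0, :] = 0  # occupancy 11/12 for all; filter at 0.99 removes all
        with pytest.raises(ValueError):
            build_network(_table_from_matrix(mat), min_prevalence=0.99)

    def test_sign_fractions_sum_to_one(self, seasonal_table):
        net = build_network(seasonal_table, min_prevalence=0.1, r_threshold=0.5)
        if net.n_edges:
            assert net.positive_fraction + net.negative_fraction == pytest.approx(1.0)


class TestTopology:
    def test_complete_graph_closed_form(self):
        m = topology_metrics(_net_from_graph(nx.complete_graph(5)))
        assert m["CC"] == 1.0 and m["APL"] == 1.0 and m["GD"] == 1.0
        assert m["ND"] == 1.0 and m["AD"] == 4.0

    def test_ring_lattice_closed_form(self):
        # 20-node ring, 2 neighbours each side: CC = 0.5, APL = 550/190
        g = nx.watts_strogatz_graph(20, 4, 0)
        m = topology_metrics(_net_from_graph(g))
        assert m["CC"] == pytest.approx(0.5)
        assert m["APL"] == pytest.approx(550 / 190)
        assert m["ND"] == 5.0

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            e = int(rng.integers(10, 40))
            adj = _random_gnm_adjacency(15, e, rng)
            m = topology_metrics(adj)
            # brute force from the adjacency matrix
            deg = adj.sum(0)
            assert m["AD"] == pytest.approx(2 * e / 15)
            assert m["GD"] == pytest.approx(2 * e / (15 * 14))
            tri = np.zeros(15)
            for i in range(15):
                nbrs = np.flatnonzero(adj[i])
                tri[i] = sum(
                    adj[u, v] for ii, u in enumerate(nbrs) for v in nbrs[ii + 1:]
                )
            local = [
                tri[i] / (deg[i] * (deg[i] - 1) / 2) if deg[i] > 1 else 0.0
                for i in range(15)
            ]
            assert m["CC"] == pytest.approx(np.mean(local))
            # Floyd-Warshall path lengths
            dist = np.where(adj, 1.0, np.inf)
            np.fill_diagonal(dist, 0)
            for k in range(15):
                dist = np.minimum(dist, dist[:, [k]] + dist[[k], :])
            off = dist[~np.eye(15, dtype=bool)]
            finite = off[np.isfinite(off)]
            assert m["APL"] == pytest.approx(finite.mean())
            assert m["ND"] == pytest.approx(finite.max())

    def test_er_null_mean_ad_exact_and_self_null_r(self):
        rng = np.random.default_rng(4)
        adj = _random_gnm_adjacency(30, 90, rng)
        net = _net_from_graph(nx.from_numpy_array(adj))
        res = topology_with_null(net, n_random=100, seed=1)
        assert res["null_means"]["AD"] == 2 * 90 / 30
        # an ER graph against its own null ensemble: r near 1
        assert 0.5 < res["small_world_r"] < 2.0

    def test_small_world_of_lattice_exceeds_one(self):
        g = nx.watts_strogatz_graph(20, 4, 0)
        res = topology_with_null(_net_from_graph(g), n_random=100, seed=2)
        assert res["small_world_r"] > 1.0

    def test_empty_graph_errors(self):
        with pytest.raises(ValueError):
            topology_metrics(np.zeros((4, 4), dtype=bool))


class TestModules:
    def test_two_disjoint_cliques(self):
        g = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(6))
        net = _net_from_graph(g)
        modules, md = detect_modules(net, seed=0)
        assert len(set(modules.values())) == 2
        assert md == pytest.approx(0.5)

    def test_single_clique_modularity_zero(self):
        net = _net_from_graph(nx.complete_graph(6))
        modules, md = detect_modules(net, seed=0)
        assert len(set(modules.values())) == 1
        assert md == pytest.approx(0.0)

    def test_major_modules_shares(self):
        g = nx.disjoint_union(nx.complete_graph(8), nx.complete_graph(4))
        modules, _ = detect_modules(_net_from_graph(g), seed=0)
        mm = major_modules(modules)
        assert mm.iloc[0]["n_nodes"] == 8
        assert mm["share"].sum() == pytest.approx(1.0)


class TestZiPi:
    def test_internal_node_pi_zero(self):
        g = nx.complete_graph(5)
        net = _net_from_graph(g)
        modules = {n: 0 for n in g.nodes}
        roles = zi_pi(net, modules)
        assert (roles["Pi"] == 0).all()

    def test_degree_four_across_four_modules(self):
        # hub node 0 connected once into each of 4 modules: Pi = 0.75
        g = nx.Graph()
        for k in range(4):
            g.add_edge(0, f"m{k}a")
            g.add_edge(f"m{k}a", f"m{k}b")
        modules = {0: 0}
        for k in range(4):
            modules[f"m{k}a"] = k + 1
            modules[f"m{k}b"] = k + 1
        roles = zi_pi(_net_from_graph(g), modules).set_index("node")
        assert roles.loc[0, "Pi"] == pytest.approx(0.75)
        assert roles.loc[0, "category"] == "connector"
        assert roles.loc[0, "keystone"]

    @pytest.mark.parametrize(
        "zi,pi,expected",
        [
            (3.0, 0.70, "network hub"),
            (3.0, 0.50, "module hub"),
            (1.0, 0.70, "connector"),
            (1.0, 0.50, "peripheral"),
            (2.5, 0.62, "network hub"),  # thresholds are inclusive for >=
        ],
    )
    def test_four_way_classification(self, zi, pi, expected):
        assert classify_role(zi, pi) == expected

    def test_sd_zero_module_flagged(self):
        g = nx.Graph([(0, 1), (1, 2), (2, 0), (2, 3)])
        modules = {0: 0, 1: 0, 2: 0, 3: 1}
        roles = zi_pi(_net_from_graph(g), modules).set_index("node")
        assert roles.loc[3, "sd_zero"]
        assert roles.loc[3, "Zi"] == 0.0
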