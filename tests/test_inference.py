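import math

import networkx as nx
import numpy as np
import pytest

import netcontrast as nc
from netcontrast.errors import SeedError
from netcontrast.inference import (
    GGN,
    InferenceParams,
    build_ggn,
    edge_flux,
    personalized_pagerank,
    select_network,
)


def pagerank_linear_solve(g, seeds, alpha):
    """Oracle: solve (I - alpha (M^T + d r^T)) pr = (1 - alpha) r directly."""
    nodes = sorted(g.nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    r = np.zeros(n)
    for s in seeds:
        r[idx[s]] = 1.0 / len(seeds)
    W = np.zeros((n, n))
    for u, v, d in g.edges(data=True):
        w = float(d.get("weight", 1.0))
        W[idx[u], idx[v]] = w
        W[idx[v], idx[u]] = w
    s = W.sum(axis=1)
    M = np.divide(W, s[:, None], out=np.zeros_like(W), where=s[:, None] > 0)
    dangling = (s == 0).astype(float)
    A = np.eye(n) - alpha * (M.T + np.outer(r, dangling))
    pr = np.linalg.solve(A, (1 - alpha) * r)
    return {u: pr[idx[u]] for u in nodes}


def random_weighted_graph(rng, n):
    g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(2**31)))
    for u, v in g.edges():
        g[u][v]["weight"] = float(rng.uniform(0.05, 1.0))
    return g


class TestPageRank:
    def test_single_node(self):
        g = nx.Graph()
        g.add_node("x")
        assert personalized_pagerank(g, ["x"], alpha=0.5) == {"x": 1.0}

    def test_two_node_closed_form(self):
        # pr_a = 0.5 + 0.5 pr_b, pr_b = 0.5 pr_a  ->  (2/3, 1/3)
        g = nx.Graph()
        g.add_edge("a", "b", weight=1.0)
        pr = personalized_pagerank(g, ["a"], alpha=0.5)
        assert pr["a"] == pytest.approx(2 / 3, abs=1e-10)
        assert pr["b"] == pytest.approx(1 / 3, abs=1e-10)

    def test_vertex_transitive_uniform(self):
        g = nx.cycle_graph(4)
        pr = personalized_pagerank(g, list(g.nodes), alpha=0.5)
        assert all(v == pytest.approx(0.25, abs=1e-10) for v in pr.values())

    def test_empty_seed_set_raises(self):
        with pytest.raises(SeedError):
            personalized_pagerank(nx.path_graph(3), [], alpha=0.5)

    def test_matches_linear_solve_on_random_graphs(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            n = int(rng.integers(2, 11))
            g = random_weighted_graph(rng, n)
            k = int(rng.integers(1, n + 1))
            seeds = list(rng.choice(n, size=k, replace=False))
            alpha = float(rng.uniform(0.1, 0.9))
            pr = personalized_pagerank(g, seeds, alpha=alpha)
            ref = pagerank_linear_solve(g, seeds, alpha)
            assert max(abs(pr[u] - ref[u]) for u in g.nodes) < 1e-10
            assert sum(pr.values()) == pytest.approx(1.0, abs=1e-12)

    def test_matches_networkx_on_connected_graph(self):
        g = random_weighted_graph(np.random.default_rng(4), 9)
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        seeds = sorted(g.nodes)[:2]
        pr = personalized_pagerank(g, seeds, alpha=0.5)
        ref = nx.pagerank(
            g, alpha=0.5, personalization={s: 1.0 for s in seeds},
            weight="weight", tol=1e-14, max_iter=1000,
        )
        assert max(abs(pr[u] - ref[u]) for u in g.nodes) < 1e-8


class TestEdgeFlux:
    def test_two_node_hand_example(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=1.0)
        pr = {"a": 2 / 3, "b": 1 / 3}
        flux = edge_flux(g, pr)
        assert flux[("a", "b")] == pytest.approx(1 / 3)

    def test_regular_graph_uniform_fluxes(self):
        g = nx.cycle_graph(6)
        pr = {u: 1 / 6 for u in g.nodes}
        flux = edge_flux(g, pr)
        vals = list(flux.values())
        assert all(v == pytest.approx(vals[0]) for v in vals)

    def test_invariant_to_global_weight_scaling(self):
        rng = np.random.default_rng(8)
        g = random_weighted_graph(rng, 8)
        pr = personalized_pagerank(g, sorted(g.nodes)[:2], alpha=0.5)
        f1 = edge_flux(g, pr)
        g2 = g.copy()
        for u, v in g2.edges():
            g2[u][v]["weight"] *= 7.5
        f2 = edge_flux(g2, pr)
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], abs=1e-12)

    def test_sum_mode(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=1.0)
        pr = {"a": 2 / 3, "b": 1 / 3}
        assert edge_flux(g, pr, mode="sum")[("a", "b")] == pytest.approx(1.0)


def _toy_ggn(fluxes):
    g = nx.Graph()
    flux = {}
    for i, f in enumerate(fluxes):
        u, v = f"n{2 * i}", f"n{2 * i + 1}"
        g.add_edge(u, v, weight=1.0)
        flux[(u, v)] = float(f)
    ggn = GGN(graph=g, significant_types={}, type_zscores={})
    pr = {u: 0.1 for u in g.nodes}
    return ggn, flux, pr


class TestSelectNetwork:
    def test_tau_quantile_keeps_top_edges(self):
        ggn, flux, pr = _toy_ggn([5, 4, 3, 2, 1])
        net = select_network(ggn, flux, pr, InferenceParams(tau=0.8), ["n0"])
        assert net.graph.number_of_edges() == 1
        assert net.edge_table().flux.iloc[0] == 5.0

    def test_tau_zero_keeps_everything_up_to_cap(self):
        ggn, flux, pr = _toy_ggn(range(1, 11))
        net = select_network(ggn, flux, pr, InferenceParams(tau=0.0), ["n0"])
        assert net.graph.number_of_edges() == 10
        capped = select_network(
            ggn, flux, pr, InferenceParams(tau=0.0, edge_cap=4), ["n0"]
        )
        assert capped.graph.number_of_edges() == 4

    def test_raising_tau_never_adds_edges(self):
        rng = np.random.default_rng(21)
        ggn, flux, pr = _toy_ggn(rng.uniform(0, 1, size=40))
        sizes = [
            select_network(
                ggn, flux, pr, InferenceParams(tau=t), ["n0"]
            ).graph.number_of_edges()
            for t in (0.0, 0.25, 0.5, 0.75, 0.9)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_empty_ggn_rejected(self):
        ggn = GGN(graph=nx.Graph(), significant_types={}, type_zscores={})
        with pytest.raises(ValueError):
            select_network(ggn, {}, {}, InferenceParams(), ["x"])

    def test_missing_seeds_reported(self):
        ggn, flux, pr = _toy_ggn([5, 4])
        net = select_network(ggn, flux, pr, InferenceParams(tau=0.6), ["n2"])
        assert "n2" in net.missing_seeds


class TestBuildGGN:
    def test_planted_clique_types_significant(self):
        # seeds inside a 6-clique stitched to a sparse ring: clique-type
        # counts collapse under rewiring, so dense types must be enriched
        g = nx.cycle_graph(range(10, 40))
        clique = nx.complete_graph(6)
        g = nx.compose(g, clique)
        g.add_edge(0, 10)
        for u, v in g.edges():
            g[u][v]["weight"] = 1.0
        params = InferenceParams(n_rewires=60, rng_seed=3)
        ggn = build_ggn(g, [0, 1], params)
        assert not ggn.fallback
        dense = {"triangle", "diamond", "clique_4", "tailed_triangle"}
        assert dense & set(ggn.significant_types)
        clique_edges = {frozenset(e) for e in clique.edges()}
        assert clique_edges <= {frozenset(e) for e in ggn.graph.edges()}
        # direct simulation of the null at higher replication agrees on
        # the enrichment call for the clique type
        from netcontrast.graphlets import (
            degree_preserving_rewire,
            enumerate_seeded_graphlets,
        )
        rng = np.random.default_rng(0)
        obs = enumerate_seeded_graphlets(g, [0, 1]).counts["clique_4"]
        null = [
            enumerate_seeded_graphlets(
                degree_preserving_rewire(g, rng=rng), [0, 1],
                store_instances=False,
            ).counts["clique_4"]
            for _ in range(300)
        ]
        null = np.asarray(null, dtype=float)
        z = (obs - null.mean()) / max(null.std(ddof=1), 1e-12)
        assert z >= params.z_threshold

    def test_fallback_to_seed_incident_edges(self):
        # a path's graphlet counts are invariant under degree-preserving
        # rewiring, so no type can be enriched and the fallback fires
        g = nx.path_graph(5)
        for u, v in g.edges():
            g[u][v]["weight"] = 1.0
        with pytest.warns(UserWarning, match="fallback|falling back"):
            ggn = build_ggn(g, [2], InferenceParams(n_rewires=20, rng_seed=0))
        assert ggn.fallback
        assert {frozenset(e) for e in ggn.graph.edges()} == {
            frozenset((2, 1)), frozenset((2, 3))
        }

    def test_ggn_edges_subset_of_interactome(self, small_dataset):
        d = small_dataset
        seeds = sorted(set(d.driver_list.gene))
        params = InferenceParams(n_rewires=5, rng_seed=2)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ggn = build_ggn(d.interactome, seeds, params)
        for u, v in ggn.graph.edges():
            assert d.interactome.has_edge(u, v)
            assert ggn.graph[u][v]["weight"] == d.interactome[u][v]["weight"]


class TestInferNetwork:
    def test_network_subset_chain_and_determinism(self, small_dataset):
        d = small_dataset
        seeds = sorted(set(d.driver_list.gene))
        params = InferenceParams(n_rewires=10, rng_seed=5)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net1 = nc.infer_network(d.interactome, seeds, params)
            net2 = nc.infer_network(d.interactome, seeds, params)
        for u, v in net1.graph.edges():
            assert net1.ggn.graph.has_edge(u, v)
            assert d.interactome.has_edge(u, v)
        assert net1.graph.number_of_edges() <= params.edge_cap
        assert net1.node_table().equals(net2.node_table())
        assert net1.edge_table().equals(net2.edge_table())

    def test_pagerank_restricted_scope(self, small_dataset):
        d = small_dataset
        seeds = sorted(set(d.driver_list.gene))[:10]
        params = InferenceParams(
            n_rewires=5, rng_seed=1, pagerank_scope="ggn"
        )
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net = nc.infer_network(d.interactome, seeds, params)
        assert net.graph.number_of_edges() > 0
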