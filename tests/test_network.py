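"""Network construction, topology oracles, degree-distribution comparison."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import comorbnet as cn
from comorbnet.network import (
    betweenness_centralization,
    degree_centralization,
    fit_discrete_exponential,
    fit_discrete_powerlaw,
)
from comorbnet.synthetic import default_catalog


def _edges_df(pairs, included=None):
    included = included if included is not None else [True] * len(pairs)
    return pd.DataFrame({
        "condition_y": [p[0] for p in pairs],
        "condition_z": [p[1] for p in pairs],
        "observed": 10, "expected": 1.0, "p_adjusted": 1e-6,
        "included": included,
    })


# --- brute-force oracles ----------------------------------------------------

def brute_density(G):
    n = G.number_of_nodes()
    return 2 * G.number_of_edges() / (n * (n - 1)) if n > 1 else 0.0


def brute_transitivity(G):
    closed = triads = 0
    for trio in itertools.combinations(G.nodes, 3):
        for a, b, c in itertools.permutations(trio, 3):
            if G.has_edge(a, b) and G.has_edge(b, c):
                triads += 1
                if G.has_edge(a, c):
                    closed += 1
    return closed / triads if triads else 0.0


def brute_betweenness(G):
    """Node betweenness via explicit shortest-path enumeration (BFS layers)."""
    nodes = list(G.nodes)
    bc = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        try:
            d = nx.shortest_path_length(G, s, t)
        except nx.NetworkXNoPath:
            continue
        paths = [p for p in nx.all_simple_paths(G, s, t, cutoff=d) if len(p) - 1 == d]
        for v in nodes:
            if v in (s, t):
                continue
            frac = sum(v in p for p in paths) / len(paths)
            bc[v] += frac
    n = len(nodes)
    norm = (n - 1) * (n - 2) / 2
    return {v: b / norm for v, b in bc.items()}


def brute_metrics(G):
    n = G.number_of_nodes()
    deg = np.array([d for _, d in G.degree()], dtype=float)
    dc = (deg.max() - deg).sum() / ((n - 1) * (n - 2)) if n > 2 else 0.0
    bvals = np.array(list(brute_betweenness(G).values()))
    bc = (bvals.max() - bvals).sum() / (n - 1) if n > 2 else 0.0
    return brute_density(G), brute_transitivity(G), dc, bc


class TestBuildNetwork:
    def test_empty_edge_table_gives_empty_network(self):
        net = cn.build_network(_edges_df([]), default_catalog(5))
        assert net.number_of_edges() == 0

    def test_triangle(self):
        net = cn.build_network(_edges_df([(0, 1), (1, 2), (0, 2)]), default_catalog(3))
        assert net.number_of_nodes() == 3 and net.number_of_edges() == 3

    def test_only_included_rows_used(self, planted_models):
        cohort, models = planted_models
        edges = cn.pairwise_comorbidity(cohort, models)
        net = cn.build_network(edges, cohort.catalog, n_dogs=cohort.n_dogs)
        expected = {
            frozenset((r.condition_y, r.condition_z))
            for r in edges[edges.included].itertuples()
        }
        assert {frozenset(e) for e in net.edges()} == expected
        for _, d in net.nodes(data=True):
            assert 0 < d["prevalence"] <= 1

    def test_include_all_nodes(self):
        net = cn.build_network(_edges_df([(0, 1)]), default_catalog(6),
                               include_all_nodes=True)
        assert net.number_of_nodes() == 6


class TestTopology:
    def test_star_extremes(self):
        star = nx.star_graph(4)  # K_{1,4}
        m = cn.topology_summary(star)
        assert m.edge_density == pytest.approx(0.4)
        assert m.degree_centralization == pytest.approx(1.0)
        assert m.betweenness_centralization == pytest.approx(1.0)
        assert m.clustering_coefficient == 0.0

    def test_complete_graph(self):
        m = cn.topology_summary(nx.complete_graph(4))
        assert m.edge_density == pytest.approx(1.0)
        assert m.degree_centralization == pytest.approx(0.0)
        assert m.betweenness_centralization == pytest.approx(0.0)
        assert m.clustering_coefficient == pytest.approx(1.0)

    def test_exhaustive_small_graphs_match_brute_force(self):
        """All graphs on 4 nodes + random graphs up to 12 nodes."""
        graphs = []
        for bits in range(64):
            G = nx.Graph()
            G.add_nodes_from(range(4))
            for idx, (a, b) in enumerate(itertools.combinations(range(4), 2)):
                if bits >> idx & 1:
                    G.add_edge(a, b)
            graphs.append(G)
        rng = np.random.default_rng(3)
        for _ in range(15):
            n = int(rng.integers(5, 13))
            graphs.append(nx.gnp_random_graph(n, rng.uniform(0.2, 0.7),
                                              seed=int(rng.integers(1e6))))
        for G in graphs:
            m = cn.topology_summary(G)
            d, t, dc, bc = brute_metrics(G)
            assert m.edge_density == pytest.approx(d, abs=1e-12)
            assert m.clustering_coefficient == pytest.approx(t, abs=1e-12)
            assert m.degree_centralization == pytest.approx(dc, abs=1e-12)
            assert m.betweenness_centralization == pytest.approx(bc, abs=1e-9)
            assert 0 <= m.edge_density <= 1 and 0 <= m.clustering_coefficient <= 1
            assert 0 <= m.degree_centralization <= 1
            assert 0 <= m.betweenness_centralization <= 1

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            cn.topology_summary(nx.Graph([("a", "a")]))


class TestDegreeFits:
    def test_exponential_fit_recovers_rate(self):
        rng = np.random.default_rng(1)
        lam = 0.4
        x = rng.geometric(1 - np.exp(-lam), size=20000)  # support {1, 2, ...}
        fit = fit_discrete_exponential(x, xmin=1)
        assert fit.rate == pytest.approx(lam, rel=0.05)

    def test_powerlaw_fit_recovers_exponent(self):
        from scipy.stats import zipf
        x = zipf.rvs(2.5, size=20000, random_state=2)
        fit = fit_discrete_powerlaw(x, xmin=1)
        assert fit.alpha == pytest.approx(2.5, rel=0.05)

    def test_geometric_degrees_prefer_exponential(self):
        rng = np.random.default_rng(4)
        x = rng.geometric(0.25, size=160)
        cmp_ = cn.degree_fit_comparison(x)
        assert cmp_.lr_statistic < 0
        assert cmp_.preferred in (None, "exponential")

    def test_powerlaw_degrees_prefer_powerlaw(self):
        from scipy.stats import zipf
        x = zipf.rvs(2.5, size=5000, random_state=5)
        cmp_ = cn.degree_fit_comparison(x)
        assert cmp_.lr_statistic > 0 and cmp_.preferred == "power_law"

    def test_constant_degrees_rejected(self):
        with pytest.raises(ValueError):
            cn.degree_fit_comparison(np.full(50, 4))

    def test_min_node_floor(self):
        with pytest.raises(ValueError):
            cn.degree_fit_comparison(np.array([1, 2, 3]))


class TestEdgeOverlap:
    def test_identical_networks(self):
        G = nx.Graph([(0, 1), (1, 2)])
        mat = cn.edge_overlap({"a": G, "b": G.copy()})
        assert mat.loc["a", "b"] == mat.loc["a", "a"] == 2

    def test_disjoint_networks(self):
        mat = cn.edge_overlap({"a": nx.Graph([(0, 1)]), "b": nx.Graph([(2, 3)])})
        assert mat.loc["a", "b"] == 0

    def test_matches_set_intersection_and_is_symmetric(self):
        rng = np.random.default_rng(6)
        nets = {
            f"n{i}": nx.gnp_random_graph(10, 0.3, seed=int(rng.integers(1e6)))
            for i in range(3)
        }
        mat = cn.edge_overlap(nets)
        assert (mat.to_numpy() == mat.to_numpy().T).all()
        for a in nets:
            for b in nets:
                brute = len({frozenset(e) for e in nets[a].edges()}
                            & {frozenset(e) for e in nets[b].edges()})
                assert mat.loc[a, b] == brute
            assert (mat.loc[a] <= mat.loc[a, a]).all()


class TestAggregate:
    def _net(self):
        G = nx.Graph()
        for n, cat in [(0, "skin"), (1, "skin"), (2, "eye"), (3, "eye"), (4, "cardiac")]:
            G.add_node(n, name=f"c{n}", category=cat)
        G.add_edges_from([(0, 1), (0, 2), (1, 3), (2, 3), (3, 4)])
        return G

    def test_within_category_edges_become_counted_self_loops(self):
        H = cn.aggregate_category_nodes(self._net(), ["skin", "eye"])
        assert H.graph["within_category_edges"] == 2  # (0,1) and (2,3)
        assert H.has_edge("category::skin", "category::eye")
        assert H.number_of_nodes() == 3

    def test_two_fully_connected_categories_collapse_to_one_edge(self):
        G = nx.Graph()
        for n in range(4):
            G.add_node(n, category="skin" if n < 2 else "eye")
        G.add_edges_from([(a, b) for a in (0, 1) for b in (2, 3)])
        H = cn.aggregate_category_nodes(G, ["skin", "eye"])
        assert H.number_of_edges() == 1

    def test_isolated_supernode(self):
        G = nx.Graph()
        G.add_node(0, category="skin")
        G.add_node(1, category="eye")
        H = cn.aggregate_category_nodes(G, ["skin"])
        assert H.degree("category::skin") == 0

    def test_contraction_matches_brute_force(self):
        G = self._net()
        H = cn.aggregate_category_nodes(G, ["skin"])
        mapping = {n: "category::skin" if G.nodes[n]["category"] == "skin" else n
                   for n in G}
        brute = {frozenset((mapping[a], mapping[b])) for a, b in G.edges()
                 if mapping[a] != mapping[b]}
        assert {frozenset(e) for e in H.edges()} == brute

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            cn.aggregate_category_nodes(self._net(), ["nope"])


def test_graphml_export_deterministic(tmp_path, planted_models):
    cohort, models = planted_models
    edges = cn.pairwise_comorbidity(cohort, models)
    net = cn.build_network(edges, cohort.catalog, n_dogs=cohort.n_dogs)
    p1, p2 = tmp_path / "a.graphml", tmp_path / "b.graphml"
    cn.network.write_graphml(net, p1)
    cn.network.write_graphml(net, p2)
    assert p1.read_bytes() == p2.read_bytes()
    back = nx.read_graphml(p1)
    assert back.number_of_edges() == net.number_of_edges()
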