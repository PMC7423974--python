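"""Correlation networks and architecture statistics against closed forms
and brute-force oracles."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cytoarch as ca
from cytoarch import network as nw
from cytoarch import simulate as sim
from conftest import iter_set_partitions


def net_from_edges(edges, vertices=None, threshold=0.6, group="g"):
    """Hand-built network: edges as (u, v, r)."""
    g = nx.Graph()
    if vertices:
        g.add_nodes_from(vertices)
    for u, v, r in edges:
        g.add_edge(u, v, r=float(r), sign=1 if r > 0 else -1, abs_r=abs(float(r)))
    return nw.ImmunomeNetwork(graph=g, threshold=threshold, group=group,
                              method="spearman")


def random_freq_table(seed, n_samples=8, n_nodes=6):
    rng = np.random.default_rng(seed)
    freq = pd.DataFrame(rng.dirichlet(np.ones(n_nodes), size=n_samples),
                        columns=range(1, n_nodes + 1))
    freq.index = [f"s{i}" for i in range(n_samples)]
    return freq


class TestBuildNetwork:
    def test_adjacency_matches_bruteforce_correlation(self):
        """Edges equal direct pairwise Spearman thresholding on a toy table."""
        freq = random_freq_table(0, n_samples=6, n_nodes=5)
        net = nw.build_network(freq, threshold=0.6)
        for u, v in itertools.combinations(freq.columns, 2):
            r = stats.spearmanr(freq[u], freq[v]).statistic
            if abs(r) > 0.6:
                assert net.graph.has_edge(u, v)
                assert net.graph[u][v]["r"] == pytest.approx(float(r))
                assert net.graph[u][v]["sign"] == (1 if r > 0 else -1)
            else:
                assert not net.graph.has_edge(u, v)

    def test_edge_signs_follow_correlation_sign(self):
        # planted exact correlations: col2 = col1 (r=1), col3 = -col1 (r=-1)
        base = np.array([0.1, 0.2, 0.3, 0.4])
        freq = pd.DataFrame({1: base, 2: base * 2, 3: base[::-1]})
        freq[4] = 1.0 - freq[[1, 2, 3]].sum(axis=1)
        net = nw.build_network(freq, threshold=0.6, method="pearson")
        assert net.graph[1][2]["sign"] == 1
        assert net.graph[1][3]["sign"] == -1

    def test_threshold_one_gives_edgeless(self):
        net = nw.build_network(random_freq_table(1), threshold=1.0)
        assert net.n_edges == 0

    def test_zero_variance_node_excluded(self, caplog):
        freq = random_freq_table(2).copy()
        freq[3] = 0.1
        with caplog.at_level("WARNING"):
            net = nw.build_network(freq, threshold=0.6)
        assert 3 in net.excluded and 3 not in net.graph

    def test_requires_four_samples(self):
        with pytest.raises(ValueError, match="4 samples"):
            nw.build_network(random_freq_table(0).iloc[:3])

    def test_threshold_monotonicity(self):
        for seed in range(10):
            freq = random_freq_table(seed)
            lo = nw.build_network(freq, threshold=0.6)
            hi = nw.build_network(freq, threshold=0.7)
            assert hi.n_edges <= lo.n_edges
            assert set(hi.graph.edges) <= set(lo.graph.edges)

    def test_sample_order_invariance(self):
        freq = random_freq_table(3)
        a = nw.build_network(freq)
        b = nw.build_network(freq.sample(frac=1, random_state=1))
        assert set(a.graph.edges) == set(b.graph.edges)


class TestModularity:
    def test_two_disconnected_cliques_give_half(self):
        """Two equal disconnected cliques: Q = 1 - 1/k = 0.5."""
        edges = [(u, v, 0.9) for u, v in itertools.combinations([1, 2, 3, 4], 2)]
        edges += [(u, v, 0.9) for u, v in itertools.combinations([5, 6, 7, 8], 2)]
        net = net_from_edges(edges)
        q, comms = nw.modularity(net)
        assert q == pytest.approx(0.5, abs=1e-12)
        assert sorted(sorted(c) for c in comms) == [[1, 2, 3, 4], [5, 6, 7, 8]]

    def test_single_community_partition_gives_zero(self):
        edges = [(1, 2, 0.8), (2, 3, 0.7), (3, 1, 0.9), (3, 4, 0.65)]
        net = net_from_edges(edges)
        assert nw.modularity_of_partition(net, [{1, 2, 3, 4}]) == \
            pytest.approx(0.0, abs=1e-12)

    def test_detected_q_bounded_by_exhaustive_maximum(self):
        """Greedy Q never exceeds the best of all 203 partitions of a
        6-vertex graph (and is within range of it on these toys)."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            edges = [(u, v, rng.uniform(0.61, 0.95) * rng.choice([-1, 1]))
                     for u, v in itertools.combinations(range(6), 2)
                     if rng.random() < 0.5]
            if not edges:
                continue
            net = net_from_edges(edges, vertices=range(6))
            q, _ = nw.modularity(net)
            best = max(nw.modularity_of_partition(net, p)
                       for p in iter_set_partitions(list(range(6))))
            assert q <= best + 1e-12

    def test_q_within_theoretical_range(self):
        for seed in range(10):
            freq = random_freq_table(seed, n_samples=6)
            net = nw.build_network(freq, threshold=0.5)
            if net.n_edges == 0:
                continue
            q, _ = nw.modularity(net)
            assert -0.5 - 1e-9 <= q <= 1.0

    def test_edgeless_q_undefined(self, caplog):
        net = net_from_edges([], vertices=[1, 2, 3])
        with caplog.at_level("WARNING"):
            q, comms = nw.modularity(net)
        assert np.isnan(q) and comms is None

    def test_louvain_agrees_on_clean_cliques(self):
        edges = [(u, v, 0.9) for u, v in itertools.combinations([1, 2, 3], 2)]
        edges += [(u, v, 0.9) for u, v in itertools.combinations([4, 5, 6], 2)]
        net = net_from_edges(edges)
        q, _ = nw.modularity(net, seed=0, algorithm="louvain")
        assert q == pytest.approx(0.5, abs=1e-12)

    def test_planted_partition_beats_random_partition(self):
        """On planted-module cohorts the true block partition scores higher
        Q than a randomly scrambled equal-size partition (>=99% of seeds)."""
        wins = trials = 0
        for seed in range(60):
            spec = sim.default_cohort_spec(seed=seed)
            obs, _ = ca.sample_observed_frequencies(spec)
            net = nw.build_network(obs.iloc[:20], group="SSc")
            if net.n_edges == 0:
                continue
            planted = ca.planted_network_truth(spec, "SSc")
            rng = np.random.default_rng(seed)
            pops = [p for block in planted for p in block]
            shuffled = rng.permutation(pops)
            random_part, i = [], 0
            for block in planted:
                random_part.append(set(shuffled[i:i + len(block)]))
                i += len(block)
            trials += 1
            wins += (nw.modularity_of_partition(net, planted) >
                     nw.modularity_of_partition(net, random_part))
        assert trials >= 50
        assert wins / trials >= 0.99


class TestCentralization:
    def test_star_is_one(self):
        edges = [(0, i, 0.9) for i in range(1, 7)]
        assert nw.centralization(net_from_edges(edges)) == pytest.approx(1.0)

    def test_complete_graph_is_zero(self):
        edges = [(u, v, 0.9) for u, v in itertools.combinations(range(5), 2)]
        assert nw.centralization(net_from_edges(edges)) == pytest.approx(0.0)

    def test_hand_computed_six_vertex_graph(self):
        # path 0-1-2-3 plus pendant 4,5 on vertex 1: degrees 1,4,2,1,1,1
        edges = [(0, 1, .7), (1, 2, .7), (2, 3, .7), (1, 4, .7), (1, 5, .7)]
        net = net_from_edges(edges)
        degrees = [1, 4, 2, 1, 1, 1]
        expected = sum(4 - d for d in degrees) / (5 * 4)
        assert nw.centralization(net) == pytest.approx(expected)

    def test_needs_three_vertices(self):
        with pytest.raises(ValueError, match=">= 3"):
            nw.centralization(net_from_edges([(1, 2, 0.9)]))


class TestNegativeEdges:
    def test_fractions(self):
        all_pos = net_from_edges([(1, 2, .7), (2, 3, .8)])
        assert nw.negative_edge_fraction(all_pos) == 0.0
        mixed = net_from_edges(
            [(i, i + 10, -0.7) for i in range(3)] +
            [(i + 20, i + 30, 0.7) for i in range(7)])
        assert nw.negative_edge_fraction(mixed) == pytest.approx(30.0)

    def test_edgeless_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = nw.negative_edge_fraction(net_from_edges([], vertices=[1, 2]))
        assert out == 0.0 and "edgeless" in caplog.text


class TestCompareArchitectures:
    def test_identical_inputs_identical_rows(self):
        freq = random_freq_table(4)
        a = nw.build_network(freq, group="A")
        b = nw.build_network(freq, group="B")
        out = nw.compare_architectures(a, b)
        assert out.loc["A"].tolist() == out.loc["B"].tolist()

    def test_mismatched_thresholds_rejected(self):
        freq = random_freq_table(4)
        a = nw.build_network(freq, threshold=0.6)
        b = nw.build_network(freq, threshold=0.7)
        with pytest.raises(ValueError, match="threshold"):
            nw.compare_architectures(a, b)


def test_graphml_and_edge_list_roundtrip(tmp_path):
    net = net_from_edges([(1, 2, 0.8), (2, 3, -0.7)])
    el = nw.edge_list(net)
    assert set(el.columns) == {"source", "target", "r", "sign"}
    assert len(el) == 2
    path = tmp_path / "net.graphml"
    nw.to_graphml(net, path)
    back = nx.read_graphml(path)
    assert back.number_of_edges() == 2
    assert back.graph["threshold"] == 0.6
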