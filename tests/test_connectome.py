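"""Connectivity matrices, density thresholding, and the global graph
diagnostics, validated against brute-force oracles."""

import math

import networkx as nx
import numpy as np
import pytest

from connlearn.connectome import (
    ConnectivityMatrix,
    DegenerateGraphError,
    DensityShortfallError,
    assortativity,
    binarize_at_density,
    build_ensemble,
    characteristic_path_length,
    correlation_matrix,
    edge_count_at_density,
    global_efficiency,
    mean_connectivity,
    metrics_over_densities,
    modularity_q,
    n_candidate_edges,
    small_worldness,
    transitivity,
)
from oracles import (
    brute_assortativity,
    brute_char_path_length,
    brute_global_efficiency,
    brute_max_modularity,
    brute_transitivity,
)


def _cm_from_upper(n, entries):
    m = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    m[iu, ju] = entries
    m = m + m.T
    return ConnectivityMatrix(values=m)


class TestCorrelationMatrix:
    def test_identical_and_negated_columns(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=50)
        ts = np.column_stack([a, a, -a])
        cm = correlation_matrix(ts)
        assert cm.values[0, 1] == pytest.approx(1.0)
        assert cm.values[0, 2] == pytest.approx(-1.0)
        assert np.all(np.diag(cm.values) == 0.0)

    def test_four_frame_toy_value(self):
        # Pearson r of (1,2,3,4) vs (1,2,3,5) computed by the closed form
        x = np.array([1.0, 2, 3, 4])
        y = np.array([1.0, 2, 3, 5])
        expected = (np.sum((x - x.mean()) * (y - y.mean()))
                    / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
        cm = correlation_matrix(np.column_stack([x, y]))
        assert expected == pytest.approx(0.98270763, abs=1e-7)
        assert cm.values[0, 1] == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_node_named(self):
        ts = np.column_stack([np.arange(10.0), np.ones(10)])
        with pytest.raises(ValueError, match="zero-variance"):
            correlation_matrix(ts)

    def test_symmetry_enforced(self):
        bad = np.array([[0.0, 0.5], [0.4, 0.0]])
        with pytest.raises(ValueError):
            ConnectivityMatrix(values=bad)


class TestBinarize:
    def test_top_k_positive_selection(self):
        cm = _cm_from_upper(4, [0.9, 0.8, 0.5, 0.3, 0.1, -0.2])
        g = binarize_at_density(cm, 1 / 3)
        # (0,1)=0.9 and (0,2)=0.8 are the two strongest positive pairs
        assert set(g.edges()) == {(0, 1), (0, 2)}

    def test_density_covering_all_positive_entries(self):
        cm = _cm_from_upper(5, [0.5, 0.4, 0.3, -0.1, -0.2, -0.3, 0.2, -0.4, -0.5, -0.6])
        g = binarize_at_density(cm, 0.4)
        assert g.number_of_edges() == 4
        assert all(cm.values[i, j] > 0 for i, j in g.edges())

    def test_candidate_edge_count_264_nodes(self):
        assert n_candidate_edges(264) == 34716

    def test_shortfall_raises(self):
        cm = _cm_from_upper(5, [-0.5] * 10)
        with pytest.raises(DensityShortfallError):
            binarize_at_density(cm, 0.2)

    def test_deterministic_tie_break(self):
        cm = _cm_from_upper(4, [0.5, 0.5, 0.5, 0.5, 0.5, 0.5])
        g = binarize_at_density(cm, 2 / 6)
        assert sorted(g.edges()) == [(0, 1), (0, 2)]

    def test_edge_count_rounding(self):
        assert edge_count_at_density(0.01, 264) == round(0.01 * 34716)
        assert edge_count_at_density(1 / 3, 4) == 2


class TestMetricWorkedExamples:
    def test_transitivity_triangle_path_chord(self):
        assert transitivity(nx.complete_graph(3)) == 1.0
        assert transitivity(nx.path_graph(3)) == 0.0
        chord = nx.Graph([(1, 2), (2, 3), (3, 4), (4, 1), (1, 3)])
        assert transitivity(chord) == pytest.approx(0.75)

    def test_path_length_examples(self):
        assert characteristic_path_length(nx.complete_graph(5)) == 1.0
        assert characteristic_path_length(nx.path_graph(3)) == pytest.approx(4 / 3)
        two_edges = nx.Graph([(0, 1), (2, 3)])
        assert characteristic_path_length(two_edges) == 1.0  # finite pairs only

    def test_efficiency_examples(self):
        assert global_efficiency(nx.complete_graph(6)) == 1.0
        assert global_efficiency(nx.path_graph(3)) == pytest.approx(5 / 6)
        g = nx.Graph()
        g.add_nodes_from(range(4))
        assert global_efficiency(g) == 0.0

    def test_edgeless_path_length_raises(self):
        g = nx.Graph()
        g.add_nodes_from(range(3))
        with pytest.raises(ValueError):
            characteristic_path_length(g)

    def test_assortativity_examples(self):
        star = nx.star_graph(3)
        assert assortativity(star) == pytest.approx(-1.0)
        assert assortativity(nx.path_graph(4)) == pytest.approx(-0.5)
        with pytest.raises(DegenerateGraphError):
            assortativity(nx.cycle_graph(4))

    def test_modularity_two_triangles(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        q, assign = modularity_q(g, seed=0)
        assert q == pytest.approx(0.5)
        assert assign == (0, 0, 0, 1, 1, 1)

    def test_modularity_clique_nonnegative(self):
        q, _ = modularity_q(nx.complete_graph(6), seed=0)
        assert q >= 0.0
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_modularity_beats_singletons(self):
        g = nx.erdos_renyi_graph(12, 0.3, seed=5)
        q, _ = modularity_q(g, seed=0)
        m = g.number_of_edges()
        q_singletons = -sum((d / (2 * m)) ** 2 for _, d in g.degree())
        assert q >= q_singletons


class TestSmallWorldness:
    def test_complete_graph_is_its_own_null(self):
        sigma, gamma, lam = small_worldness(nx.complete_graph(10), n_random=5, seed=0)
        assert sigma == gamma == lam == 1.0

    def test_watts_strogatz_is_small_world(self):
        g = nx.watts_strogatz_graph(100, 4, 0.1, seed=7)
        sigma, gamma, lam = small_worldness(g, n_random=20, seed=1)
        assert sigma > 1.0
        assert gamma > 1.0

    def test_dense_random_graph_near_unity(self):
        g = nx.erdos_renyi_graph(100, 0.3, seed=9)
        sigma, _, _ = small_worldness(g, n_random=10, seed=2)
        assert 0.8 < sigma < 1.2

    def test_rewiring_preserves_degrees(self):
        g = nx.erdos_renyi_graph(30, 0.2, seed=3)
        from connlearn.connectome import _rewire

        h = _rewire(g, np.random.default_rng(0), 10 * g.number_of_edges())
        assert sorted(dict(g.degree()).values()) == sorted(dict(h.degree()).values())
        assert h.number_of_edges() == g.number_of_edges()

    def test_too_small_component_raises(self):
        with pytest.raises(ValueError):
            small_worldness(nx.path_graph(3), n_random=5, seed=0)


@pytest.fixture(scope="module")
def random_graphs():
    rng = np.random.default_rng(42)
    graphs = []
    for _ in range(30):
        g = nx.erdos_renyi_graph(8, rng.uniform(0.25, 0.7), seed=int(rng.integers(1 << 30)))
        if g.number_of_edges() >= 2:
            graphs.append(g)
    return graphs


class TestBruteForceAgreement:
    """The production metrics agree with exhaustive/naive oracles on random
    8-node graphs."""

    def test_transitivity_matches(self, random_graphs):
        for g in random_graphs:
            assert transitivity(g) == pytest.approx(
                brute_transitivity(list(g.edges()), 8), abs=1e-12
            )

    def test_path_length_and_efficiency_match(self, random_graphs):
        for g in random_graphs:
            edges = list(g.edges())
            assert characteristic_path_length(g) == pytest.approx(
                brute_char_path_length(edges, 8), abs=1e-12
            )
            assert global_efficiency(g) == pytest.approx(
                brute_global_efficiency(edges, 8), abs=1e-12
            )

    def test_modularity_matches_exhaustive_max(self, random_graphs):
        for g in random_graphs:
            q, _ = modularity_q(g, seed=0)
            assert q == pytest.approx(brute_max_modularity(list(g.edges()), 8), abs=1e-9)

    def test_assortativity_matches(self, random_graphs):
        for g in random_graphs:
            try:
                expected = brute_assortativity(list(g.edges()), 8)
            except ValueError:
                continue
            assert assortativity(g) == pytest.approx(expected, abs=1e-10)


@pytest.fixture(scope="module")
def cm():
    rng = np.random.default_rng(8)
    ts = rng.normal(size=(120, 24))
    # add modular structure so mid densities cluster
    for block in range(4):
        shared = rng.normal(size=120)
        ts[:, block * 6 : (block + 1) * 6] += 0.8 * shared[:, None]
    return correlation_matrix(ts)


class TestEnsembleAndAveraging:

    def test_nestedness_across_densities(self, cm):
        ens = build_ensemble(cm, densities=np.array([0.10, 0.20, 0.40]))
        e1, e2, e3 = (set(g.edges()) for g in ens.graphs)
        assert e1 <= e2 <= e3

    def test_efficiency_nondecreasing_in_density(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            ts = rng.normal(size=(60, 12))
            cm = correlation_matrix(ts)
            dens = np.array([0.1, 0.2, 0.3, 0.4])
            effs = [global_efficiency(binarize_at_density(cm, d)) for d in dens]
            assert all(a <= b + 1e-12 for a, b in zip(effs, effs[1:]))

    def test_constant_metric_average_is_constant(self, cm):
        ms = metrics_over_densities(
            cm, densities=np.array([0.2, 0.3]), n_random=3, seed=0
        )
        per = ms.per_density
        for name in ("transitivity", "global_efficiency"):
            assert ms.averaged[name] == pytest.approx(per[name].mean())

    def test_mean_connectivity_is_off_diagonal_mean(self, cm):
        iu, ju = np.triu_indices(cm.n_nodes, k=1)
        assert mean_connectivity(cm) == pytest.approx(cm.values[iu, ju].mean())

    def test_sigma_exceeds_one_on_modular_structure(self, cm):
        ms = metrics_over_densities(
            cm, densities=np.array([0.15, 0.25]), n_random=10, seed=1
        )
        assert ms.averaged["small_worldness"] > 1.0
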