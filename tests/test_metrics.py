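"""Efficiency metrics against exhaustive enumeration, plus cost-grid summaries."""

import numpy as np
import pytest

from gmvnet import (
    DEFAULT_COST_GRID,
    global_efficiency,
    local_efficiency,
    node_strength,
    profile_from_correlation,
    summary_over_costs,
    threshold_by_cost,
)
from gmvnet.metrics import summary_metric_from_correlation
from oracles import (
    exhaustive_global_efficiency,
    exhaustive_local_efficiency,
    exhaustive_node_strength,
    random_weighted_graph,
)


def _graph(edges, n):
    W = np.zeros((n, n))
    for i, j, w in edges:
        W[i, j] = W[j, i] = w
    return W


def test_single_edge_efficiency():
    assert global_efficiency(_graph([(0, 1, 0.5)], 2)) == pytest.approx(0.5)


def test_complete_unit_graph_efficiency_one():
    W = 1.0 - np.eye(5)
    assert global_efficiency(W) == pytest.approx(1.0)
    assert local_efficiency(W) == pytest.approx(1.0)


def test_three_node_path():
    W = _graph([(0, 1, 1.0), (1, 2, 1.0)], 3)
    assert global_efficiency(W) == pytest.approx(5 / 6)


def test_triangle_and_star_local_efficiency():
    tri = _graph([(0, 1, 1), (1, 2, 1), (0, 2, 1)], 3)
    assert local_efficiency(tri) == pytest.approx(1.0)
    star = _graph([(0, j, 1.0) for j in range(1, 6)], 6)
    assert local_efficiency(star) == 0.0


def test_k4_minus_edge_matches_oracle():
    W = 1.0 - np.eye(4)
    W[0, 1] = W[1, 0] = 0.0
    assert local_efficiency(W) == pytest.approx(exhaustive_local_efficiency(W), abs=1e-12)


def test_node_strength_sums_weights():
    W = _graph([(0, 1, 0.5), (0, 2, 0.3)], 4)
    np.testing.assert_allclose(node_strength(W), [0.8, 0.5, 0.3, 0.0])


def test_metrics_match_exhaustive_oracle_on_small_graphs(rng):
    for _ in range(50):
        W = random_weighted_graph(rng, max_nodes=6)
        assert global_efficiency(W) == pytest.approx(
            exhaustive_global_efficiency(W), abs=1e-12
        )
        assert local_efficiency(W) == pytest.approx(
            exhaustive_local_efficiency(W), abs=1e-12
        )
        np.testing.assert_allclose(node_strength(W), exhaustive_node_strength(W), atol=1e-12)


def test_global_efficiency_matches_networkx(rng):
    """Second independent route: networkx Dijkstra on 1/w edge lengths."""
    nx = pytest.importorskip("networkx")
    for _ in range(5):
        W = random_weighted_graph(rng, max_nodes=8)
        n = W.shape[0]
        G = nx.Graph()
        G.add_nodes_from(range(n))
        for i, j in zip(*np.nonzero(np.triu(W, 1))):
            G.add_edge(int(i), int(j), length=1.0 / W[i, j])
        total = 0.0
        for i, dists in nx.all_pairs_dijkstra_path_length(G, weight="length"):
            total += sum(1.0 / d for j, d in dists.items() if j != i and d > 0)
        expected = total / (n * (n - 1)) if n > 1 else 0.0
        assert global_efficiency(W) == pytest.approx(expected, abs=1e-12)


def test_metrics_scale_linearly_with_weights(rng):
    W = random_weighted_graph(rng, max_nodes=6)
    c = 3.7
    assert global_efficiency(c * W) == pytest.approx(c * global_efficiency(W), rel=1e-12)
    assert local_efficiency(c * W) == pytest.approx(c * local_efficiency(W), rel=1e-12)
    np.testing.assert_allclose(node_strength(c * W), c * node_strength(W), rtol=1e-12)


def test_adding_an_edge_never_decreases_ge_or_ns(rng):
    for _ in range(20):
        W = random_weighted_graph(rng, max_nodes=6)
        free = np.argwhere(np.triu(W == 0, k=1))
        if free.size == 0:
            continue
        i, j = free[rng.integers(len(free))]
        W2 = W.copy()
        W2[i, j] = W2[j, i] = rng.uniform(0.05, 1.0)
        assert global_efficiency(W2) >= global_efficiency(W) - 1e-12
        assert (node_strength(W2) >= node_strength(W) - 1e-12).all()


def test_default_cost_grid():
    assert len(DEFAULT_COST_GRID) == 15
    assert DEFAULT_COST_GRID[0] == pytest.approx(0.11)
    assert DEFAULT_COST_GRID[-1] == pytest.approx(0.25)
    np.testing.assert_allclose(np.diff(DEFAULT_COST_GRID), 0.01)


def test_summary_is_arithmetic_mean(rng):
    X = rng.normal(size=(40, 12))
    r = np.corrcoef(X, rowvar=False)
    labels = [str(i) for i in range(12)]
    nets = [threshold_by_cost(r, t, labels=labels) for t in (0.2, 0.3, 0.4)]
    prof = summary_over_costs(nets)
    assert prof.summary_ge == pytest.approx(prof.ge.mean())
    assert prof.summary_le == pytest.approx(prof.le.mean())
    np.testing.assert_allclose(prof.summary_ns, prof.ns.mean(axis=0))
    ge = [global_efficiency(n) for n in nets]
    assert prof.summary_ge == pytest.approx(np.mean(ge))


def test_profile_incremental_equals_per_network(rng):
    """The nested incremental profile equals independently thresholded networks."""
    X = rng.normal(size=(60, 20))
    r = np.corrcoef(X, rowvar=False)
    labels = [str(i) for i in range(20)]
    grid = np.array([0.12, 0.18, 0.24])
    prof = profile_from_correlation(r, grid, labels=labels)
    for k, t in enumerate(grid):
        net = threshold_by_cost(r, float(t), labels=labels)
        assert prof.ge[k] == pytest.approx(global_efficiency(net), abs=1e-12)
        assert prof.le[k] == pytest.approx(local_efficiency(net), abs=1e-12)
        np.testing.assert_allclose(prof.ns[k], node_strength(net), atol=1e-12)
    # batched Floyd-Warshall fast path agrees with the Dijkstra route
    assert summary_metric_from_correlation(r, "GE", grid) == pytest.approx(
        prof.summary_ge, abs=1e-12
    )
    assert summary_metric_from_correlation(r, "LE", grid) == pytest.approx(
        prof.summary_le, abs=1e-12
    )


def test_empty_grid_errors(rng):
    X = rng.normal(size=(10, 5))
    with pytest.raises(ValueError):
        profile_from_correlation(np.corrcoef(X, rowvar=False), np.array([]))
    with pytest.raises(ValueError):
        summary_over_costs([])
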