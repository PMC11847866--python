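"""Correlation network: thresholding, centralities, layout, exports."""

import itertools
import json
import math
from xml.etree import ElementTree as ET

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nssinet.cohort import one_hot_encode
from nssinet.network import (
    CorrelationNetwork,
    LayoutParams,
    NetworkError,
    betweenness_centrality,
    centralities,
    correlation_matrix,
    degree_centrality,
    edge_styles,
    network_density,
    pairwise_pearson,
    rank_nodes,
    spring_layout,
    threshold_adjacency,
    to_json_dict,
    write_graphml,
    write_json,
)


def _net(r, theta=None):
    labels = tuple(f"n{i}" for i in range(r.shape[0]))
    net = CorrelationNetwork(labels, np.asarray(r, float))
    return net.threshold(theta) if theta is not None else net


# ---------------------------------------------------------------------------
# correlations


def test_perfectly_aligned_and_opposed_columns():
    x = np.array([[0, 0], [0, 0], [1, 1], [1, 1.0]])
    assert pairwise_pearson(x)[0, 1] == pytest.approx(1.0)
    y = np.array([[0, 1], [0, 1], [1, 0], [1, 0.0]])
    assert pairwise_pearson(y)[0, 1] == pytest.approx(-1.0)


def test_binary_correlation_equals_phi_coefficient():
    a, b, c, d = 32, 13, 15, 50
    n = a + b + c + d
    x = np.repeat([1.0, 1.0, 0.0, 0.0], [a, b, c, d])
    y = np.repeat([1.0, 0.0, 1.0, 0.0], [a, b, c, d])
    r = pairwise_pearson(np.column_stack([x, y]))[0, 1]
    chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    phi = math.copysign(math.sqrt(chi2 / n), a * d - b * c)
    assert r == pytest.approx(phi, abs=1e-12)


def test_phi_identity_holds_for_every_pair_of_encoded_columns(cohort_112):
    """Pairwise r on complete binary data matches the 2x2 phi coefficient."""
    enc = one_hot_encode(cohort_112)
    values = enc.values
    r = pairwise_pearson(values)
    cols = [5, 9, 15, 18, 22, 23, 24]  # a spread of blocks incl. SC/SS
    for i, j in itertools.combinations(cols, 2):
        both = ~np.isnan(values[:, i]) & ~np.isnan(values[:, j])
        x, y = values[both, i], values[both, j]
        a = np.sum((x == 1) & (y == 1))
        b = np.sum((x == 1) & (y == 0))
        c = np.sum((x == 0) & (y == 1))
        d = np.sum((x == 0) & (y == 0))
        denom = (a + b) * (c + d) * (a + c) * (b + d)
        if denom == 0:
            assert np.isnan(r[i, j]) or r[i, j] == 0
            continue
        phi = (a * d - b * c) / math.sqrt(denom)
        assert r[i, j] == pytest.approx(phi, abs=1e-10)


def test_zero_variance_column_is_masked_not_guessed():
    x = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 0.0]])
    r = pairwise_pearson(x)
    assert np.isnan(r[0, 1])


def test_all_missing_column_is_an_error(tiny_cohort):
    enc = one_hot_encode(tiny_cohort)
    enc.values[:, 0] = np.nan
    with pytest.raises(NetworkError, match="FE1"):
        correlation_matrix(enc)


# ---------------------------------------------------------------------------
# threshold / density / degree


def test_threshold_is_strict_and_absolute():
    r = np.array([[1.0, 0.21, 0.20], [0.21, 1.0, -0.25], [0.20, -0.25, 1.0]])
    adj = threshold_adjacency(r, 0.2)
    assert adj[0, 1] == 1  # 0.21 > 0.2
    assert adj[0, 2] == 0  # 0.20 is not > 0.2
    assert adj[1, 2] == 1  # |-0.25| > 0.2
    assert np.diag(adj).sum() == 0


@given(st.floats(0.0, 0.5), st.floats(0.0, 0.5))
def test_thresholding_is_monotone_in_theta(t1, t2):
    rng = np.random.default_rng(0)
    r = rng.uniform(-1, 1, (6, 6))
    r = (r + r.T) / 2
    np.fill_diagonal(r, 1.0)
    lo, hi = min(t1, t2), max(t1, t2)
    assert (threshold_adjacency(r, hi) <= threshold_adjacency(r, lo)).all()


@pytest.mark.parametrize(
    "n, e, expected", [(4, 6, 1.0), (3, 2, 2 / 3), (25, 60, 0.2)]
)
def test_density_formula(n, e, expected):
    assert network_density(n, e) == pytest.approx(expected)


def test_degree_is_row_sums_and_totals_twice_edges():
    adj = np.array(
        [[0, 1, 1, 0], [1, 0, 1, 0], [1, 1, 0, 1], [0, 0, 1, 0]]
    )
    deg = degree_centrality(adj)
    assert deg.tolist() == [2, 2, 3, 1]
    assert deg.sum() == 2 * (adj.sum() // 2)


# ---------------------------------------------------------------------------
# betweenness


def path_graph(n):
    adj = np.zeros((n, n), int)
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = 1
    return adj


def test_betweenness_on_small_named_graphs():
    # path a-b-c: the middle carries the single {a,c} pair
    assert betweenness_centrality(path_graph(3)).tolist() == [0.0, 1.0, 0.0]
    # star with 3 leaves: the hub carries all 3 leaf pairs
    star = np.zeros((4, 4), int)
    star[0, 1:] = star[1:, 0] = 1
    assert betweenness_centrality(star).tolist() == [3.0, 0.0, 0.0, 0.0]
    # 5-cycle: each node is the unique middle of exactly one distance-2 pair
    cycle = path_graph(5)
    cycle[0, 4] = cycle[4, 0] = 1
    assert betweenness_centrality(cycle).tolist() == [1.0] * 5
    # disconnected pairs contribute nothing
    two = np.zeros((4, 4), int)
    two[0, 1] = two[1, 0] = 1
    assert betweenness_centrality(two).tolist() == [0.0] * 4


def brute_force_betweenness(adj):
    """Enumerate every simple path per pair; count shortest ones per node."""
    n = adj.shape[0]
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = []
        stack = [(s, [s])]
        while stack:
            v, path = stack.pop()
            if v == t:
                paths.append(path)
                continue
            for w in range(n):
                if adj[v, w] and w not in path:
                    stack.append((w, path + [w]))
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        sp = [p for p in paths if len(p) == shortest]
        for node in range(n):
            if node in (s, t):
                continue
            through = sum(node in p for p in sp)
            bc[node] += through / len(sp)
    return bc


def test_betweenness_matches_brute_force_and_networkx():
    import networkx as nx

    rng = np.random.default_rng(5)
    for _ in range(25):
        n = int(rng.integers(3, 8))
        adj = (rng.random((n, n)) < 0.45).astype(int)
        adj = np.triu(adj, 1)
        adj = adj + adj.T
        mine = betweenness_centrality(adj)
        np.testing.assert_allclose(mine, brute_force_betweenness(adj), atol=1e-12)
        ref = nx.betweenness_centrality(nx.from_numpy_array(adj), normalized=False)
        np.testing.assert_allclose(mine, [ref[i] for i in range(n)], atol=1e-12)


def test_rank_nodes_descending_with_frozen_tie_order():
    labels = ("a", "b", "c")
    assert rank_nodes(labels, np.array([3, 1, 2])) == ["a", "c", "b"]
    assert rank_nodes(labels, np.array([1, 1, 1])) == ["a", "b", "c"]
    # relabelling permutes the ranking identically (up to tie policy)
    values = np.array([5, 2, 9])
    perm = [2, 0, 1]
    permuted = rank_nodes(tuple(labels[i] for i in perm), values[perm])
    assert permuted == rank_nodes(labels, values)


# ---------------------------------------------------------------------------
# edge styles


def test_edge_styles_widths_and_signs():
    r = np.array([[1.0, -0.5, 0.0], [-0.5, 1.0, 0.9], [0.0, 0.9, 1.0]])
    styles = {(s.i, s.j): s for s in edge_styles(_net(r), omega=10.0)}
    assert styles[(0, 1)].width == pytest.approx(5.0)
    assert styles[(0, 1)].sign == "negative"
    assert styles[(0, 2)].width == 0.0
    assert styles[(1, 2)].sign == "positive"
    widths = [s.width for s in sorted(styles.values(), key=lambda s: abs(s.r))]
    assert widths == sorted(widths)  # monotone in |r|


# ---------------------------------------------------------------------------
# spring layout


def test_attraction_vanishes_at_desired_distance():
    """Two connected nodes exactly d0 apart barely move (zero spring force)."""
    r = np.array([[1.0, 0.5], [0.5, 1.0]])
    net = _net(r, theta=0.2)
    params = LayoutParams(d0=1.0, c=1e-12, movement_tolerance=1e-6)
    init = np.array([[0.0, 0.0], [1.0, 0.0]])
    result = spring_layout(net, params, initial_positions=init)
    assert result.converged
    assert result.iterations_run == 1
    np.testing.assert_allclose(result.positions, init, atol=1e-9)


def test_single_node_layout_is_trivial():
    net = _net(np.array([[1.0]]))
    result = spring_layout(net)
    assert result.converged
    assert result.iterations_run == 0


def test_layout_deterministic_under_seed():
    rng = np.random.default_rng(1)
    r = rng.uniform(-1, 1, (6, 6))
    r = (r + r.T) / 2
    np.fill_diagonal(r, 1.0)
    net = _net(r, theta=0.2)
    a = spring_layout(net, LayoutParams(seed=11))
    b = spring_layout(net, LayoutParams(seed=11))
    np.testing.assert_array_equal(a.positions, b.positions)
    c = spring_layout(net, LayoutParams(seed=12))
    assert not np.array_equal(a.positions, c.positions)


def test_coincident_nodes_are_jittered_not_divided():
    r = np.array([[1.0, 0.5], [0.5, 1.0]])
    net = _net(r, theta=0.2)
    init = np.zeros((2, 2))
    result = spring_layout(net, LayoutParams(max_iterations=50), initial_positions=init)
    assert np.isfinite(result.positions).all()


# ---------------------------------------------------------------------------
# full-network plumbing


def test_full_25_node_network_and_exports(tmp_path, cohort_112):
    net = correlation_matrix(one_hot_encode(cohort_112)).threshold(0.2)
    assert net.n_nodes == 25
    assert 0.0 <= net.density <= 1.0
    cent = centralities(net)
    assert cent.degree.sum() == 2 * net.n_edges
    table = cent.table()
    assert set(table.columns) >= {"node", "degree", "betweenness"}
    # exports parse
    gpath = tmp_path / "net.graphml"
    write_graphml(net, gpath, positions=np.zeros((25, 2)))
    tree = ET.parse(gpath)
    assert tree.getroot().tag.endswith("graphml")
    jpath = tmp_path / "net.json"
    write_json(net, jpath)
    data = json.loads(jpath.read_text())
    assert len(data["nodes"]) == 25
    assert data["theta"] == 0.2
    d = to_json_dict(net)
    assert d["density"] == net.density
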