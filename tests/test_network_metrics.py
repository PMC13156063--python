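import numpy as np
import pytest

from neurofuse.gsngc import ConnectivityMatrix
from neurofuse.network_metrics import (
    BrainGraph,
    characteristic_path_length,
    clustering_coefficient,
    global_efficiency,
    graph_metrics,
    local_efficiency,
    metric_table,
    to_graph,
)


def floyd_warshall_oracle(adj: np.ndarray) -> np.ndarray:
    """Brute-force all-pairs shortest paths on distance = 1/weight."""
    n = adj.shape[0]
    with np.errstate(divide="ignore"):
        D = np.where(adj > 0, 1.0 / adj, np.inf)
    np.fill_diagonal(D, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                D[i, j] = min(D[i, j], D[i, k] + D[k, j])
    return D


def binary(adj):
    return to_graph(adj, mode="binary")


K4 = np.ones((4, 4)) - np.eye(4)
STAR4 = np.zeros((4, 4))
STAR4[0, 1:] = STAR4[1:, 0] = 1
PATH3 = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
TRI_PENDANT = np.zeros((4, 4))
TRI_PENDANT[:3, :3] = 1 - np.eye(3)
TRI_PENDANT[2, 3] = TRI_PENDANT[3, 2] = 1
# triangle plus an isolated 4th node
TRI_ISOLATED = np.zeros((4, 4))
TRI_ISOLATED[:3, :3] = 1 - np.eye(3)


class TestHandValues:
    def test_k4(self):
        g = binary(K4)
        assert clustering_coefficient(g)[0] == pytest.approx(1.0)
        assert characteristic_path_length(g)[0] == pytest.approx(1.0)
        assert global_efficiency(g)[0] == pytest.approx(1.0)
        assert local_efficiency(g)[0] == pytest.approx(1.0)

    def test_star(self):
        g = binary(STAR4)
        assert clustering_coefficient(g)[0] == pytest.approx(0.0)
        # (6*1 + 6*2)/12
        assert characteristic_path_length(g)[0] == pytest.approx(1.5)
        # (6*1 + 6*0.5)/12
        assert global_efficiency(g)[0] == pytest.approx(0.75)
        assert local_efficiency(g)[0] == pytest.approx(0.0)

    def test_path3(self):
        g = binary(PATH3)
        assert characteristic_path_length(g)[0] == pytest.approx(4.0 / 3.0)

    def test_triangle_plus_attached_pendant(self):
        g = binary(TRI_PENDANT)
        cc, nodal = clustering_coefficient(g)
        # node 2 gains the pendant: degree 3, one closed pair of three
        np.testing.assert_allclose(nodal, [1.0, 1.0, 1.0 / 3.0, 0.0])
        assert cc == pytest.approx((1 + 1 + 1 / 3 + 0) / 4)

    def test_triangle_plus_isolated_node(self):
        g = binary(TRI_ISOLATED)
        cc, nodal = clustering_coefficient(g)
        np.testing.assert_allclose(nodal, [1.0, 1.0, 1.0, 0.0])
        assert cc == pytest.approx(0.75)

    def test_edgeless(self):
        g = binary(np.zeros((4, 4)))
        assert global_efficiency(g)[0] == 0.0


class TestToGraph:
    def test_symmetrize_rule(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = 2.0
        g = to_graph(adj, normalize=False)
        assert g.adjacency[0, 1] == pytest.approx(1.0)
        assert g.adjacency[1, 0] == pytest.approx(1.0)
        assert g.distance[0, 1] == pytest.approx(1.0)

    def test_symmetric_unchanged(self, rng):
        adj = np.abs(rng.standard_normal((5, 5)))
        adj = (adj + adj.T) / 2
        np.fill_diagonal(adj, 0)
        g = to_graph(adj, normalize=False)
        np.testing.assert_allclose(g.adjacency, adj)

    def test_negative_rejected(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = -1
        with pytest.raises(ValueError):
            to_graph(adj)


class TestOracle:
    def test_floyd_warshall_equivalence(self, rng):
        for _ in range(100):
            adj = np.abs(rng.standard_normal((8, 8)))
            adj[rng.random((8, 8)) < 0.4] = 0.0
            adj = (adj + adj.T) / 2
            np.fill_diagonal(adj, 0)
            g = BrainGraph(adj, mode="weighted", labels=[str(i) for i in range(8)])
            D_oracle = floyd_warshall_oracle(adj)
            off = ~np.eye(8, dtype=bool)
            finite = np.isfinite(D_oracle) & off
            cpl, _, _ = characteristic_path_length(g)
            if finite.any():
                assert cpl == pytest.approx(D_oracle[finite].mean(), abs=1e-10)
            inv = np.where(np.isfinite(D_oracle) & (D_oracle > 0), 1 / D_oracle, 0)
            assert global_efficiency(g)[0] == pytest.approx(
                inv[off].mean(), abs=1e-10
            )

    def test_local_efficiency_oracle(self, rng):
        for _ in range(100):
            adj = np.abs(rng.standard_normal((8, 8)))
            adj[rng.random((8, 8)) < 0.5] = 0.0
            adj = (adj + adj.T) / 2
            np.fill_diagonal(adj, 0)
            g = BrainGraph(adj, mode="weighted", labels=[str(i) for i in range(8)])
            _, nodal = local_efficiency(g)
            for i in range(8):
                nbrs = np.flatnonzero(adj[i] > 0)
                if nbrs.size < 2:
                    assert nodal[i] == 0.0
                    continue
                sub = adj[np.ix_(nbrs, nbrs)]
                D = floyd_warshall_oracle(sub)
                k = nbrs.size
                off = ~np.eye(k, dtype=bool)
                inv = np.where(np.isfinite(D) & (D > 0), 1 / D, 0)
                expected = inv[off].sum() / (k * (k - 1))
                assert nodal[i] == pytest.approx(expected, abs=1e-10)


class TestProperties:
    def test_adding_edge_never_decreases_ge(self, rng):
        adj = np.abs(rng.standard_normal((6, 6)))
        adj[rng.random((6, 6)) < 0.6] = 0.0
        adj = (adj + adj.T) / 2
        np.fill_diagonal(adj, 0)
        g = to_graph(adj, normalize=False)
        ge0 = global_efficiency(g)[0]
        zeros = np.argwhere((adj == 0) & ~np.eye(6, dtype=bool))
        i, j = zeros[0]
        adj2 = adj.copy()
        adj2[i, j] = adj2[j, i] = 0.5
        assert global_efficiency(to_graph(adj2, normalize=False))[0] >= ge0

    def test_weight_scaling(self, rng):
        adj = np.abs(rng.standard_normal((6, 6)))
        adj = (adj + adj.T) / 2
        np.fill_diagonal(adj, 0)
        ge1 = global_efficiency(to_graph(adj, normalize=False))[0]
        ge3 = global_efficiency(to_graph(3 * adj, normalize=False))[0]
        assert ge3 == pytest.approx(3 * ge1)
        # with max-normalization metrics are scale-free
        ge_n1 = global_efficiency(to_graph(adj))[0]
        ge_n3 = global_efficiency(to_graph(3 * adj))[0]
        assert ge_n1 == pytest.approx(ge_n3)

    def test_node_permutation_invariance(self, rng):
        adj = np.abs(rng.standard_normal((8, 8)))
        adj = (adj + adj.T) / 2
        np.fill_diagonal(adj, 0)
        perm = rng.permutation(8)
        g1 = graph_metrics(to_graph(adj))
        g2 = graph_metrics(to_graph(adj[np.ix_(perm, perm)]))
        for attr in ("CC", "CPL", "GE", "LE"):
            assert getattr(g1, attr) == pytest.approx(getattr(g2, attr))


def test_metric_table_shape(rng):
    conn = {}
    for s in ("sub-000", "sub-001"):
        mats = {}
        for band in ("delta", "theta", "alpha", "beta"):
            m = np.abs(rng.standard_normal((8, 8)))
            np.fill_diagonal(m, 0)
            mats[band] = m
        conn[s] = ConnectivityMatrix(matrices=mats, labels=[f"c{i}" for i in range(8)])
    glob, nodal = metric_table(conn)
    assert len(glob) == 2 * 4 * 4
    assert len(nodal) == 2 * 4 * 4 * 8
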