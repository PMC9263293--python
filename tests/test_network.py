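"""Graph-metric tests, each backed by an independent brute-force oracle."""

import itertools

import numpy as np
import pytest

from plvnet.connectivity import PLVMatrix
from plvnet.errors import (
    DegenerateNetworkError,
    DisconnectedNetworkError,
    InvalidParameterError,
)
from plvnet.network import (
    BinaryNetwork,
    SparsityGrid,
    binarize,
    characteristic_path_length,
    clustering_coefficient,
    edge_count,
    global_efficiency,
    local_efficiency,
    metric_sweep,
    nodal_degrees,
    shortest_path_lengths,
)
from plvnet.preprocess import DEFAULT_MONTAGE

from .conftest import random_symmetric_matrix


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive)
# ---------------------------------------------------------------------------


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def oracle_L(adj: np.ndarray) -> tuple[float, int]:
    d = floyd_warshall(adj)
    vals = [
        d[i, j]
        for i, j in itertools.combinations(range(adj.shape[0]), 2)
        if np.isfinite(d[i, j])
    ]
    if not vals:
        raise ZeroDivisionError
    return float(np.mean(vals)), len(vals)


def oracle_eglobal(adj: np.ndarray) -> float:
    n = adj.shape[0]
    d = floyd_warshall(adj)
    total = sum(
        1.0 / d[i, j]
        for i in range(n)
        for j in range(n)
        if i != j and np.isfinite(d[i, j])
    )
    return total / (n * (n - 1))


def oracle_clustering(adj: np.ndarray) -> tuple[float, list[float]]:
    n = adj.shape[0]
    cs = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            cs.append(0.0)
            continue
        e = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if adj[a, b]
        )
        cs.append(2.0 * e / (k * (k - 1)))
    return float(np.mean(cs)), cs


def oracle_elocal(adj: np.ndarray) -> float:
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        if len(nbrs) < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        total += oracle_eglobal(sub)
    return total / n


def net_from_edges(n, edges):
    adj = np.zeros((n, n), dtype=int)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    return BinaryNetwork(adjacency=adj, sparsity=0.5)


def random_net(n, p, seed):
    rng = np.random.default_rng(seed)
    adj = (rng.random((n, n)) < p).astype(int)
    adj = np.triu(adj, 1)
    adj = adj + adj.T
    return BinaryNetwork(adjacency=adj, sparsity=0.5)


K3 = net_from_edges(3, [(0, 1), (1, 2), (0, 2)])
PATH3 = net_from_edges(3, [(0, 1), (1, 2)])
STAR4 = net_from_edges(4, [(0, 1), (0, 2), (0, 3)])
K4 = net_from_edges(4, list(itertools.combinations(range(4), 2)))
K4_MINUS_EDGE = net_from_edges(4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3)])


# ---------------------------------------------------------------------------
# binarize
# ---------------------------------------------------------------------------


class TestBinarize:
    def test_edge_count_paper_grid_arithmetic(self):
        assert edge_count(0.12, 30) == 52  # round(0.12 * 435)

    def test_realized_k_exact_across_default_grid(self, rng):
        mat = random_symmetric_matrix(30, rng)
        for s in SparsityGrid.default():
            net = binarize(mat, s)
            assert net.k_edges == edge_count(s, 30)

    def test_single_edge_is_max_pair(self, rng):
        mat = random_symmetric_matrix(10, rng)
        iu, ju = np.triu_indices(10, 1)
        top = np.argmax(mat[iu, ju])
        net = binarize(mat, 1.0 / 45 + 1e-9)  # K = 1
        assert net.k_edges == 1
        assert net.adjacency[iu[top], ju[top]] == 1

    def test_tie_broken_lexicographically(self):
        mat = np.eye(4)
        # (0,3) and (1,2) tied at 0.5; (0,1) strictly higher
        mat[0, 1] = mat[1, 0] = 0.9
        mat[0, 3] = mat[3, 0] = 0.5
        mat[1, 2] = mat[2, 1] = 0.5
        net = binarize(mat, 2.0 / 6 + 1e-9)  # K = 2
        assert net.k_edges == 2
        assert net.adjacency[0, 1] == 1
        assert net.adjacency[0, 3] == 1  # (0,3) < (1,2) lexicographically
        assert net.adjacency[1, 2] == 0

    def test_nesting_across_grid(self, rng):
        for seed in range(10):
            mat = random_symmetric_matrix(15, np.random.default_rng(seed))
            prev = None
            for s in (0.1, 0.2, 0.3, 0.5):
                adj = binarize(mat, s).adjacency
                if prev is not None:
                    assert np.all(adj >= prev)  # edge sets nested
                prev = adj

    def test_zero_edges_rejected(self):
        mat = np.eye(3)
        with pytest.raises(DegenerateNetworkError):
            binarize(mat, 0.01)

    def test_sparsity_bounds_rejected(self, rng):
        mat = random_symmetric_matrix(5, rng)
        for s in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(InvalidParameterError):
                binarize(mat, s)

    def test_masked_entries_rank_last(self, rng):
        mat = random_symmetric_matrix(5, rng)
        mask = np.zeros((5, 5), dtype=bool)
        mask[0, 1] = mask[1, 0] = True
        plv = PLVMatrix(
            values=mat, channel_labels=list("ABCDE"), mask=mask
        )
        # K = 9 of 10 edges: the masked pair must be the one left out
        net = binarize(plv, 0.9)
        assert net.adjacency[0, 1] == 0
        assert net.k_edges == 9


# ---------------------------------------------------------------------------
# metrics: closed forms and oracles
# ---------------------------------------------------------------------------


class TestShortestPaths:
    def test_complete_graph_all_ones(self):
        d = shortest_path_lengths(K4)
        off = d[~np.eye(4, dtype=bool)]
        assert np.all(off == 1)

    def test_path_graph(self):
        d = shortest_path_lengths(PATH3)
        assert d[0, 2] == 2

    @pytest.mark.parametrize("seed", range(100))
    def test_agrees_with_floyd_warshall(self, seed):
        net = random_net(10, 0.3, seed)
        np.testing.assert_array_equal(
            shortest_path_lengths(net), floyd_warshall(net.adjacency)
        )


class TestCharacteristicPathLength:
    def test_triangle(self):
        assert characteristic_path_length(K3)[0] == 1.0

    def test_path3(self):
        L, n_conn = characteristic_path_length(PATH3)
        assert L == pytest.approx(4.0 / 3.0)
        assert n_conn == 3

    def test_star4(self):
        assert characteristic_path_length(STAR4)[0] == pytest.approx(1.5)

    def test_fully_disconnected_raises(self):
        net = BinaryNetwork(adjacency=np.zeros((4, 4), dtype=int), sparsity=0.1)
        with pytest.raises(DisconnectedNetworkError):
            characteristic_path_length(net)

    def test_disconnected_pairs_excluded_and_counted(self):
        # edge (0,1) plus isolated nodes 2, 3
        net = net_from_edges(4, [(0, 1)])
        L, n_conn = characteristic_path_length(net)
        assert L == 1.0
        assert n_conn == 1


class TestGlobalEfficiency:
    def test_triangle_is_one(self):
        assert global_efficiency(K3) == pytest.approx(1.0)

    def test_path3(self):
        assert global_efficiency(PATH3) == pytest.approx(5.0 / 6.0)

    def test_isolates_contribute_zero(self):
        net = net_from_edges(4, [(0, 1)])
        # ordered pairs: (0,1), (1,0) -> 1 each; rest 0
        assert global_efficiency(net) == pytest.approx(2.0 / 12.0)


class TestClustering:
    def test_triangle_is_one(self):
        assert clustering_coefficient(K3)[0] == 1.0

    def test_star_is_zero(self):
        assert clustering_coefficient(STAR4)[0] == 0.0

    def test_k4_minus_edge(self):
        # enumeration oracle confirms 5/6: nodes 0,1 have C_i = 2/3;
        # nodes 2,3 have C_i = 1
        c, c_i = clustering_coefficient(K4_MINUS_EDGE)
        oc, oc_i = oracle_clustering(K4_MINUS_EDGE.adjacency)
        assert c == pytest.approx(5.0 / 6.0)
        assert oc == pytest.approx(5.0 / 6.0)
        np.testing.assert_allclose(c_i, oc_i)


class TestLocalEfficiency:
    def test_k4_is_one(self):
        assert local_efficiency(K4) == pytest.approx(1.0)

    def test_star_is_zero(self):
        assert local_efficiency(STAR4) == 0.0

    @pytest.mark.parametrize("seed", range(100))
    def test_agrees_with_subgraph_oracle(self, seed):
        net = random_net(10, 0.4, seed)
        assert local_efficiency(net) == pytest.approx(
            oracle_elocal(net.adjacency), abs=1e-12
        )


class TestNodalDegrees:
    def test_star_degrees(self):
        labels = ["FP1", "FP2", "F3", "F4"]
        prof = nodal_degrees(STAR4, DEFAULT_MONTAGE, labels)
        assert list(prof.degrees) == [3, 1, 1, 1]
        assert prof.mean_degree == 1.5
        assert prof.lobe_means["frontal"] == 1.5

    @pytest.mark.parametrize("seed", range(50))
    def test_handshake_and_row_sum_oracle(self, seed):
        net = random_net(30, 0.2, seed)
        labels = DEFAULT_MONTAGE.channels
        prof = nodal_degrees(net, DEFAULT_MONTAGE, labels)
        assert prof.degrees.sum() == 2 * net.k_edges
        np.testing.assert_array_equal(
            prof.degrees, [net.adjacency[i].sum() for i in range(30)]
        )

    def test_label_mismatch_raises(self):
        from plvnet.errors import MontageError

        with pytest.raises(MontageError):
            nodal_degrees(STAR4, DEFAULT_MONTAGE, ["FP1"])


class TestCompleteGraphIdentity:
    @pytest.mark.parametrize("n", [3, 4, 5, 6, 8])
    def test_all_metrics_one(self, n):
        net = net_from_edges(n, list(itertools.combinations(range(n), 2)))
        assert characteristic_path_length(net)[0] == 1.0
        assert clustering_coefficient(net)[0] == 1.0
        assert global_efficiency(net) == pytest.approx(1.0)
        assert local_efficiency(net) == pytest.approx(1.0)


class TestBruteForceAgreement:
    """All four global metrics vs. naive oracles on random small graphs."""

    @pytest.mark.parametrize("seed", range(100))
    def test_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        net = random_net(n, float(rng.uniform(0.2, 0.7)), seed + 10_000)
        try:
            expected_L, expected_n = oracle_L(net.adjacency)
            L, n_conn = characteristic_path_length(net)
            assert L == expected_L
            assert n_conn == expected_n
        except ZeroDivisionError:
            with pytest.raises(DisconnectedNetworkError):
                characteristic_path_length(net)
        assert clustering_coefficient(net)[0] == oracle_clustering(net.adjacency)[0]
        assert global_efficiency(net) == pytest.approx(
            oracle_eglobal(net.adjacency), abs=1e-12
        )
        assert local_efficiency(net) == pytest.approx(
            oracle_elocal(net.adjacency), abs=1e-12
        )


# ---------------------------------------------------------------------------
# sweep
# ---------------------------------------------------------------------------


class TestSparsityGrid:
    def test_default_grid_29_values(self):
        grid = SparsityGrid.default()
        assert len(grid) == 29
        assert grid.values[0] == pytest.approx(0.12)
        assert grid.values[-1] == pytest.approx(0.40)

    def test_invalid_grids_rejected(self):
        with pytest.raises(InvalidParameterError):
            SparsityGrid((0.3, 0.2))
        with pytest.raises(InvalidParameterError):
            SparsityGrid((0.0, 0.2))
        with pytest.raises(InvalidParameterError):
            SparsityGrid(())


class TestMetricSweep:
    @pytest.fixture(scope="class")
    def plv30(self):
        mat = random_symmetric_matrix(30, np.random.default_rng(77))
        return PLVMatrix(
            values=mat,
            channel_labels=DEFAULT_MONTAGE.channels,
            subject_id="S1",
        )

    def test_default_grid_gives_29_rows(self, plv30):
        g_df, n_df = metric_sweep(plv30)
        assert len(g_df) == 29
        # nodal: 29 sparsities x 30 channels + 30 across-grid means
        assert len(n_df) == 29 * 30 + 30

    def test_eglobal_monotone_along_grid(self, plv30):
        g_df, _ = metric_sweep(plv30)
        eg = g_df.sort_values("sparsity")["Eglobal"].to_numpy()
        assert np.all(np.diff(eg) >= -1e-12)

    def test_identical_matrices_identical_rows(self, plv30):
        g1, _ = metric_sweep(plv30)
        g2, _ = metric_sweep(plv30)
        assert g1.equals(g2)

    def test_mean_degree_rows_average_grid(self, plv30):
        _, n_df = metric_sweep(plv30)
        per_thr = n_df[n_df["sparsity"] != "mean"]
        means = n_df[n_df["sparsity"] == "mean"].set_index("channel")["degree"]
        expected = per_thr.groupby("channel")["degree"].mean()
        for ch in means.index:
            assert means[ch] == pytest.approx(expected[ch])

    def test_metric_bounds(self, plv30):
        g_df, _ = metric_sweep(plv30)
        for col in ("C", "Eglobal", "Elocal"):
            assert ((g_df[col] >= 0) & (g_df[col] <= 1)).all()
        assert (g_df["L"] >= 1).all()
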