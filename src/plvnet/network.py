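"""Sparsity-thresholded binary networks and their graph metrics.

Sparsity is the fraction of realized edges K over the N(N-1)/2 possible
edges of an undirected graph.  Binarization keeps the K strongest PLV
entries; metrics are the standard binary-graph quantities: characteristic
path length L (mean shortest-path hop count over connected pairs), global
efficiency (mean reciprocal distance, 1/inf = 0), clustering coefficient
(mean triangle density around nodes, 0 for degree < 2), local efficiency
(mean global efficiency of each node's neighbor-induced subgraph), and
node degree with lobe aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .connectivity import PLVMatrix
from .errors import (
    DegenerateNetworkError,
    DisconnectedNetworkError,
    InvalidParameterError,
    MontageError,
)
from .preprocess import Montage

__all__ = [
    "BinaryNetwork",
    "SparsityGrid",
    "GlobalMetrics",
    "NodalDegreeProfile",
    "binarize",
    "shortest_path_lengths",
    "characteristic_path_length",
    "global_efficiency",
    "clustering_coefficient",
    "local_efficiency",
    "nodal_degrees",
    "metric_sweep",
    "max_edges",
    "edge_count",
]


def max_edges(n_nodes: int) -> int:
    return n_nodes * (n_nodes - 1) // 2


def edge_count(sparsity: float, n_nodes: int) -> int:
    """K = round(sparsity * N(N-1)/2), rounding half away from zero."""
    return int(np.floor(sparsity * max_edges(n_nodes) + 0.5))


@dataclass
class BinaryNetwork:
    """Undirected, unweighted adjacency at a stated sparsity."""

    adjacency: np.ndarray
    sparsity: float

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise InvalidParameterError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise InvalidParameterError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise InvalidParameterError("adjacency diagonal must be zero")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def k_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)


@dataclass(frozen=True)
class SparsityGrid:
    """Strictly increasing sparsity values in (0, 1)."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size == 0:
            raise InvalidParameterError("empty sparsity grid")
        if np.any(v <= 0) or np.any(v >= 1):
            raise InvalidParameterError("sparsity values must lie in (0, 1)")
        if np.any(np.diff(v) <= 0):
            raise InvalidParameterError("sparsity grid must be strictly increasing")

    def __iter__(self):
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def default(cls) -> "SparsityGrid":
        """0.12 to 0.40 inclusive in steps of 0.01 (29 values)."""
        return cls.from_range(0.12, 0.40, 0.01)

    @classmethod
    def from_range(cls, low: float, high: float, step: float) -> "SparsityGrid":
        n = int(round((high - low) / step)) + 1
        return cls(tuple(round(low + k * step, 10) for k in range(n)))


@dataclass(frozen=True)
class GlobalMetrics:
    L: float
    C: float
    Eglobal: float
    Elocal: float
    n_connected_pairs: int


@dataclass
class NodalDegreeProfile:
    degrees: np.ndarray
    channel_labels: list[str]
    lobes: dict[str, str]
    mean_degree: float
    lobe_means: dict[str, float]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def binarize(plv_matrix: PLVMatrix | np.ndarray, sparsity: float) -> BinaryNetwork:
    """Threshold a PLV matrix into a binary network of fixed sparsity.

    The K = round(sparsity * N(N-1)/2) largest off-diagonal upper-triangle
    entries become edges.  Ties at the cutoff are broken by lexicographic
    (i, j) order, so edge sets are nested along increasing sparsity.
    Masked (undefined) entries rank last.
    """
    if not 0 < sparsity < 1:
        raise InvalidParameterError(f"sparsity {sparsity} outside (0, 1)")
    if isinstance(plv_matrix, PLVMatrix):
        values = plv_matrix.values
        mask = plv_matrix.mask
    else:
        values = np.asarray(plv_matrix, dtype=float)
        mask = np.zeros(values.shape, dtype=bool)
    n = values.shape[0]
    if not np.allclose(values, values.T, atol=1e-12):
        raise InvalidParameterError("PLV matrix must be symmetric")
    k = edge_count(sparsity, n)
    if k == 0:
        raise DegenerateNetworkError(
            f"sparsity {sparsity} yields zero edges on N = {n}"
        )
    iu, ju = np.triu_indices(n, 1)
    vals = values[iu, ju].copy()
    vals[mask[iu, ju]] = -np.inf  # undefined entries rank last
    # sort by value descending, then (i, j) ascending: stable lexicographic
    order = np.lexsort((ju, iu, -vals))
    adj = np.zeros((n, n), dtype=np.int8)
    sel = order[:k]
    adj[iu[sel], ju[sel]] = 1
    adj[ju[sel], iu[sel]] = 1
    return BinaryNetwork(adjacency=adj, sparsity=sparsity)


def shortest_path_lengths(network: BinaryNetwork) -> np.ndarray:
    """Hop-count distance matrix (BFS); unreachable pairs are inf."""
    return _csgraph_shortest_path(
        network.adjacency.astype(float), method="D", unweighted=True, directed=False
    )


def characteristic_path_length(
    network: BinaryNetwork, distances: np.ndarray | None = None
) -> tuple[float, int]:
    """Mean shortest-path length over connected pairs.

    Returns ``(L, n_connected_pairs)`` where the count is over unordered
    pairs with finite distance.  Raises if no pair is connected.
    """
    d = shortest_path_lengths(network) if distances is None else distances
    iu, ju = np.triu_indices(network.n_nodes, 1)
    vals = d[iu, ju]
    finite = np.isfinite(vals)
    n_conn = int(finite.sum())
    if n_conn == 0:
        raise DisconnectedNetworkError(
            "no connected node pair; characteristic path length undefined"
        )
    return float(vals[finite].mean()), n_conn


def global_efficiency(
    network: BinaryNetwork, distances: np.ndarray | None = None
) -> float:
    """Mean reciprocal shortest-path length over all pairs (1/inf = 0)."""
    n = network.n_nodes
    if n < 2:
        return 0.0
    d = shortest_path_lengths(network) if distances is None else distances
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def clustering_coefficient(network: BinaryNetwork) -> tuple[float, np.ndarray]:
    """Network clustering coefficient C and per-node C_i.

    C_i = 2 E_i / (k_i (k_i - 1)) with E_i the edge count among node i's
    neighbors; C_i = 0 by convention for k_i < 2.  C is the mean of C_i
    over all N nodes.
    """
    a = network.adjacency.astype(np.int64)
    k = a.sum(axis=1)
    # a^3 diagonal counts closed triangles through each node (x2)
    triangles = np.diag(a @ a @ a) / 2.0
    denom = k * (k - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c_i = np.where(denom > 0, triangles / denom, 0.0)
    return float(c_i.mean()), c_i


def local_efficiency(network: BinaryNetwork) -> float:
    """Mean global efficiency of each node's neighbor-induced subgraph.

    Nodes with fewer than two neighbors contribute 0.
    """
    a = network.adjacency
    total = 0.0
    for i in range(network.n_nodes):
        nbrs = np.nonzero(a[i])[0]
        if nbrs.size < 2:
            continue
        sub = BinaryNetwork(
            adjacency=a[np.ix_(nbrs, nbrs)].copy(), sparsity=network.sparsity
        )
        total += global_efficiency(sub)
    return total / network.n_nodes


def nodal_degrees(
    network: BinaryNetwork, montage: Montage, channel_labels: list[str]
) -> NodalDegreeProfile:
    """Node degrees plus lobe-aggregated means.

    Lobe means cover the montage's lobes; per-node output covers all nodes.
    """
    if len(channel_labels) != network.n_nodes:
        raise MontageError(
            f"{len(channel_labels)} labels for {network.n_nodes} nodes"
        )
    degrees = network.degrees()
    lobes = {lab: montage.lobe_of(lab) for lab in channel_labels}
    lobe_means: dict[str, float] = {}
    for lobe in montage.lobes:
        members = [
            i for i, lab in enumerate(channel_labels) if lobes[lab] == lobe
        ]
        if members:
            lobe_means[lobe] = float(degrees[members].mean())
    return NodalDegreeProfile(
        degrees=degrees,
        channel_labels=list(channel_labels),
        lobes=lobes,
        mean_degree=float(degrees.mean()),
        lobe_means=lobe_means,
    )


def metric_sweep(
    plv_mat: PLVMatrix,
    sparsity_grid: SparsityGrid | None = None,
    montage: Montage | None = None,
    group: str = "",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute all metrics over a sparsity grid for one PLV matrix.

    Returns ``(global_df, nodal_df)``:

    * ``global_df``: one row per sparsity with columns ``subject_id, group,
      band, sparsity, L, C, Eglobal, Elocal, n_connected_pairs``.
    * ``nodal_df``: long format ``subject_id, band, sparsity, channel,
      lobe, degree`` (sparsity ``"mean"`` rows carry the across-grid mean
      degree per channel).
    """
    from .preprocess import DEFAULT_MONTAGE

    grid = sparsity_grid or SparsityGrid.default()
    montage = montage or DEFAULT_MONTAGE
    band_name = plv_mat.band.name if plv_mat.band else ""
    g_rows, n_rows = [], []
    degree_acc = np.zeros(plv_mat.n_channels)
    for s in grid:
        net = binarize(plv_mat, s)
        d = shortest_path_lengths(net)
        length, n_conn = characteristic_path_length(net, d)
        c, _ = clustering_coefficient(net)
        profile = nodal_degrees(net, montage, plv_mat.channel_labels)
        g_rows.append(
            {
                "subject_id": plv_mat.subject_id,
                "group": group,
                "band": band_name,
                "sparsity": s,
                "L": length,
                "C": c,
                "Eglobal": global_efficiency(net, d),
                "Elocal": local_efficiency(net),
                "n_connected_pairs": n_conn,
            }
        )
        degree_acc += profile.degrees
        for ch, lobe, deg in zip(
            profile.channel_labels, profile.lobes.values(), profile.degrees
        ):
            n_rows.append(
                {
                    "subject_id": plv_mat.subject_id,
                    "band": band_name,
                    "sparsity": s,
                    "channel": ch,
                    "lobe": lobe,
                    "degree": float(deg),
                }
            )
    mean_deg = degree_acc / len(grid)
    for i, ch in enumerate(plv_mat.channel_labels):
        n_rows.append(
            {
                "subject_id": plv_mat.subject_id,
                "band": band_name,
                "sparsity": "mean",
                "channel": ch,
                "lobe": montage.lobe_of(ch),
                "degree": float(mean_deg[i]),
            }
        )
    return pd.DataFrame(g_rows), pd.DataFrame(n_rows)
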