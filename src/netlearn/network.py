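"""Binary functional networks from synchronization matrices, and their
global statistics.

Networks are built by rank thresholding: the ``E = round(k * N / 2)``
strongest off-diagonal R values become edges, so every network in a study has
the same number of nodes and the same link density — node count and density
both bias the clustering coefficient and the average shortest path length, so
they are pinned rather than thresholded at a fixed numeric R.  The target mean
degree ``k`` defaults to ``ceil(2 ln N)`` (7 for N = 29), the smallest integer
satisfying the random-graph connectedness bound ``k > 2 ln N`` while keeping
the networks sparse.

A thresholded network can still disintegrate; the average shortest path
length is infinite for disconnected graphs, so construction repairs such
networks by adding the next-strongest non-edges, in rank order, until a single
component remains.  Repairs are logged and flagged because they raise the
nominal edge count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .exceptions import DisconnectedNetworkError, ParameterError
from .phase import SyncMatrix

__all__ = [
    "FunctionalNetwork",
    "WindowMetrics",
    "default_mean_degree",
    "threshold_network",
    "clustering_coefficient",
    "average_shortest_path_length",
    "window_metrics",
    "write_edgelist",
]

logger = logging.getLogger(__name__)


@dataclass
class FunctionalNetwork:
    """Binary, undirected, loop-free functional network.

    ``n_edges`` counts edges after connectedness repair; ``repaired`` is True
    when edges beyond the nominal rank cutoff were added.
    """

    adjacency: np.ndarray
    n_edges: int
    target_mean_degree: float
    repaired: bool = False
    window_index: int = -1

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def mean_degree(self) -> float:
        return 2.0 * self.n_edges / self.n_nodes


@dataclass
class WindowMetrics:
    """Global statistics of one window's network."""

    window_index: int
    clustering: float
    path_length: float


def default_mean_degree(n_nodes: int) -> int:
    """Smallest integer mean degree satisfying ``k > 2 ln N`` (7 for N=29)."""
    return math.ceil(2.0 * math.log(n_nodes))


def _ranked_pairs(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle pairs sorted by descending R, ties by ascending (j, k)."""
    n = values.shape[0]
    jj, kk = np.triu_indices(n, k=1)
    r = values[jj, kk]
    # np.lexsort: last key is primary
    order = np.lexsort((kk, jj, -r))
    return jj[order], kk[order]


def threshold_network(R: SyncMatrix, target_mean_degree: float | None = None
                      ) -> FunctionalNetwork:
    """Threshold a synchronization matrix into a connected binary network.

    The ``E = round(k*N/2)`` largest off-diagonal entries become edges (ties at
    the cutoff broken by ascending channel-index pair, deterministically).  If
    the result is disconnected, next-ranked non-edges are added one at a time
    until it is connected; the network is then flagged ``repaired``.
    """
    n = R.n_channels
    if n < 3:
        raise ParameterError(f"need at least 3 nodes, got {n}")
    if target_mean_degree is None:
        target_mean_degree = default_mean_degree(n)
    max_edges = n * (n - 1) // 2
    n_edges_target = int(np.rint(target_mean_degree * n / 2.0))
    if n_edges_target > max_edges:
        raise ParameterError(
            f"mean degree {target_mean_degree} needs {n_edges_target} edges; "
            f"only {max_edges} possible for N={n}")
    if n_edges_target < 1:
        raise ParameterError(f"mean degree {target_mean_degree} selects no edges")
    if target_mean_degree <= 2.0 * math.log(n):
        logger.warning(
            "target mean degree %.3g <= 2 ln N = %.3g; connectedness not "
            "guaranteed for random networks", target_mean_degree, 2.0 * math.log(n))

    jj, kk = _ranked_pairs(R.values)
    adj = np.zeros((n, n), dtype=np.int8)
    adj[jj[:n_edges_target], kk[:n_edges_target]] = 1
    adj |= adj.T

    n_extra = 0
    pos = n_edges_target
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    while n_comp > 1:
        if pos >= jj.size:
            raise ParameterError("ran out of candidate edges before connecting")
        j, k = jj[pos], kk[pos]
        pos += 1
        # only the strongest remaining entries that bridge distinct components
        if adj[j, k] or labels[j] == labels[k]:
            continue
        adj[j, k] = adj[k, j] = 1
        n_extra += 1
        n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    if n_extra:
        logger.info("window %d: connectedness repair added %d edge(s)",
                    R.window_index, n_extra)
    return FunctionalNetwork(
        adjacency=adj,
        n_edges=n_edges_target + n_extra,
        target_mean_degree=float(target_mean_degree),
        repaired=n_extra > 0,
        window_index=R.window_index,
    )


def clustering_coefficient(net: FunctionalNetwork) -> tuple[np.ndarray, float]:
    """Per-node and global clustering coefficient.

    ``C_i = 2 * triangles(i) / (k_i (k_i - 1))`` for degree ``k_i >= 2`` and 0
    otherwise; the global C is the mean of ``C_i`` over *all* nodes, including
    the zero-by-convention ones.
    """
    a = net.adjacency.astype(np.int64)
    deg = a.sum(axis=1)
    triangles = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    denom = deg * (deg - 1)
    per_node = np.zeros(net.n_nodes, dtype=float)
    mask = denom > 0
    per_node[mask] = 2.0 * triangles[mask] / denom[mask]
    return per_node, float(per_node.mean())


def average_shortest_path_length(net: FunctionalNetwork) -> float:
    """Mean hop count over all unordered node pairs (unit edge weights).

    Raises :class:`DisconnectedNetworkError` when any pair is unreachable.
    """
    d = shortest_path(csr_matrix(net.adjacency), method="D", directed=False,
                      unweighted=True)
    iu = np.triu_indices(net.n_nodes, k=1)
    pair_d = d[iu]
    if np.isinf(pair_d).any():
        raise DisconnectedNetworkError(
            "graph is disconnected; average shortest path length is infinite")
    return float(pair_d.mean())


def window_metrics(nets: Sequence[FunctionalNetwork]) -> list[WindowMetrics]:
    """Global C and L for each network, in input order."""
    if not nets:
        return []
    n0 = nets[0].n_nodes
    if any(net.n_nodes != n0 for net in nets):
        raise ParameterError("all networks must share the node count")
    return [
        WindowMetrics(
            window_index=net.window_index,
            clustering=clustering_coefficient(net)[1],
            path_length=average_shortest_path_length(net),
        )
        for net in nets
    ]


def write_edgelist(net: FunctionalNetwork, labels: Sequence[str], path) -> None:
    """Write the adjacency as a ``source_label,target_label`` CSV edge list."""
    if len(labels) != net.n_nodes:
        raise ParameterError(f"{len(labels)} labels for {net.n_nodes} nodes")
    jj, kk = np.nonzero(np.triu(net.adjacency, k=1))
    with open(path, "w") as fh:
        fh.write("source_label,target_label\n")
        for j, k in zip(jj, kk):
            fh.write(f"{labels[j]},{labels[k]}\n")
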