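"""Graph-topology measures on binary brain networks.

Seven measures on the OMST-binarized network: global, nodal and local
efficiency (integration at whole-graph, node and neighbourhood scale), and
degree, betweenness, eigenvector and pagerank centrality. Conventions:

* unreachable pairs contribute 0 to efficiency sums (1/inf = 0);
* betweenness sums the shortest-path fractions over *ordered* pairs
  (k, j), k != j != i, with no halving and no normalisation, so the centre
  of a 3-path scores 2;
* local efficiency of a node with fewer than 2 neighbours is 0 (the
  neighbour subgraph is degenerate);
* eigenvector centrality is the leading eigenvector of the adjacency,
  unit Euclidean norm, Perron (nonnegative) orientation;
* pagerank solves r = (1-d) 1 + d A D^{-1} r as a dense linear system
  (damping d = 0.85), which for connected graphs sums to N and equals 1 on
  every regular graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .omst import BinaryNetwork

__all__ = [
    "ShortestPathStructure",
    "NodeMetricsTable",
    "EigenPair",
    "NODE_METRICS",
    "shortest_paths",
    "global_efficiency",
    "nodal_efficiency",
    "local_efficiency",
    "degree_centrality",
    "betweenness_centrality",
    "eigenvector_centrality",
    "pagerank_centrality",
    "compute_all_metrics",
]

NODE_METRICS = ("Enodal", "Elocal", "DC", "BC", "EC", "PC")


@dataclass
class ShortestPathStructure:
    """All-pairs hop distances and shortest-path counts of a binary graph."""

    N: int
    adjacency: np.ndarray = field(repr=False)
    lengths: np.ndarray = field(repr=False)  # L[i, j], inf if unreachable
    counts: np.ndarray = field(repr=False)  # sigma[i, j], number of shortest paths

    def paths_via(self, i: int) -> np.ndarray:
        """sigma_kj(i): shortest k->j paths passing through interior node i."""
        L, sigma = self.lengths, self.counts
        with np.errstate(invalid="ignore"):
            on_path = L[:, i][:, None] + L[i, :][None, :] == L
        via = np.where(on_path, sigma[:, i][:, None] * sigma[i, :][None, :], 0.0)
        via[i, :] = 0.0
        via[:, i] = 0.0
        np.fill_diagonal(via, 0.0)
        return via


@dataclass(frozen=True)
class EigenPair:
    lambda_1: float
    mu_1: np.ndarray = field(repr=False)


@dataclass
class NodeMetricsTable:
    """Long-format per-node metrics plus the per-graph global efficiency."""

    node_table: pd.DataFrame
    eglob: float


def _as_adjacency(network) -> tuple[np.ndarray, list[str], str]:
    if isinstance(network, BinaryNetwork):
        return (
            np.asarray(network.adjacency, dtype=np.int64),
            list(network.names),
            network.subject_id,
        )
    a = np.asarray(network, dtype=np.int64)
    return a, [f"node_{i}" for i in range(a.shape[0])], ""


def shortest_paths(adjacency) -> ShortestPathStructure:
    """BFS distances and shortest-path counts via level-synchronous DP."""
    A, _, _ = _as_adjacency(adjacency)
    n = A.shape[0]
    Af = A.astype(float)
    L = np.full((n, n), np.inf)
    np.fill_diagonal(L, 0.0)
    sigma = np.eye(n)
    d = 0
    while True:
        frontier = np.where(L == d, sigma, 0.0)
        M = frontier @ Af
        new = (M > 0) & np.isinf(L)
        if not new.any():
            break
        d += 1
        L[new] = d
        sigma[new] = M[new]
    return ShortestPathStructure(N=n, adjacency=A, lengths=L, counts=sigma)


def _inv_lengths(L: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        inv = 1.0 / L
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv


def global_efficiency(sp: ShortestPathStructure | np.ndarray) -> float:
    """Mean reciprocal shortest path length over ordered pairs."""
    if not isinstance(sp, ShortestPathStructure):
        sp = shortest_paths(sp)
    n = sp.N
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    return float(_inv_lengths(sp.lengths).sum() / (n * (n - 1)))


def nodal_efficiency(sp: ShortestPathStructure, i: int) -> float:
    """Mean reciprocal distance from node i to every other node."""
    inv = _inv_lengths(sp.lengths)
    return float(inv[i].sum() / (sp.N - 1))


def local_efficiency(adjacency, i: int) -> float:
    """Global efficiency of the subgraph induced by i's neighbours."""
    A, _, _ = _as_adjacency(adjacency)
    nb = np.flatnonzero(A[i])
    if nb.size < 2:
        return 0.0
    return global_efficiency(A[np.ix_(nb, nb)])


def degree_centrality(adjacency, i: int) -> int:
    A, _, _ = _as_adjacency(adjacency)
    return int(A[i].sum())


def betweenness_centrality(sp: ShortestPathStructure, i: int) -> float:
    """Ordered-pair sum of sigma_kj(i) / sigma_kj over k != j, both != i."""
    sigma = sp.counts
    via = sp.paths_via(i)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(sigma > 0, via / np.where(sigma > 0, sigma, 1.0), 0.0)
    return float(frac.sum())


def eigenvector_centrality(
    adjacency, tol: float = 1e-10
) -> tuple[np.ndarray, EigenPair]:
    """Leading eigenvector of the adjacency (unit norm, Perron orientation)."""
    A, _, _ = _as_adjacency(adjacency)
    w, V = np.linalg.eigh(A.astype(float))
    lam = float(w[-1])
    v = V[:, -1]
    if v.sum() < 0:
        v = -v
    residual = np.max(np.abs(A @ v - lam * v))
    if residual > tol:
        raise ArithmeticError(
            f"eigenvector residual {residual:.2e} exceeds tolerance {tol:.0e}"
        )
    return v, EigenPair(lambda_1=lam, mu_1=v)


def pagerank_centrality(adjacency, d: float = 0.85) -> np.ndarray:
    """Fixed point of r = (1-d) + d A D^{-1} r, solved densely; sums to N."""
    A, _, _ = _as_adjacency(adjacency)
    deg = A.sum(axis=1)
    if np.any(deg == 0):
        raise ValueError("pagerank undefined with zero-degree nodes")
    n = A.shape[0]
    M = np.eye(n) - d * (A / deg[None, :])
    r = np.linalg.solve(M, np.full(n, 1.0 - d))
    residual = np.max(np.abs(r - ((1 - d) + d * (A / deg[None, :]) @ r)))
    if residual > 1e-12:
        raise ArithmeticError(f"pagerank residual {residual:.2e} exceeds 1e-12")
    return r


def compute_all_metrics(network) -> NodeMetricsTable:
    """All node-level measures plus global efficiency for one network.

    Returns a long-format table keyed by (subject_id, parcel, metric): the
    six node measures for every node, with the graph-level Eglob carried
    separately on the result.
    """
    A, names, subject_id = _as_adjacency(network)
    n = A.shape[0]
    sp = shortest_paths(A)
    inv = _inv_lengths(sp.lengths)
    enodal = inv.sum(axis=1) / (n - 1)
    eglob = float(enodal.mean())
    elocal = np.array([local_efficiency(A, i) for i in range(n)])
    dc = A.sum(axis=1)
    bc = np.array([betweenness_centrality(sp, i) for i in range(n)])
    ec, _ = eigenvector_centrality(A)
    pc = pagerank_centrality(A)

    values = {"Enodal": enodal, "Elocal": elocal, "DC": dc.astype(float), "BC": bc,
              "EC": ec, "PC": pc}
    rows = []
    for metric in NODE_METRICS:
        for k, name in enumerate(names):
            rows.append(
                {
                    "subject_id": subject_id,
                    "parcel": name,
                    "metric": metric,
                    "value": float(values[metric][k]),
                }
            )
    return NodeMetricsTable(node_table=pd.DataFrame(rows), eglob=eglob)
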