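"""Orthogonal minimal spanning trees (OMST): threshold-free sparsification.

Density thresholds impose an arbitrary edge count on every subject; OMST
instead extracts successive minimum spanning trees (each round excluding all
edges selected before, hence "orthogonal"), aggregates them cumulatively,
and keeps the aggregation that maximises global cost efficiency

    GCE = Eglob(selected weighted subgraph) - cost,

where cost is the selected fraction of total edge weight and Eglob uses
shortest paths on reciprocal-similarity distances (strong similarity = short
distance). The first tree guarantees connectivity; later trees add the next
strongest scaffold of edges. The selected union is binarized for downstream
topology.

Kruskal construction with a lexicographic ``(distance, i, j)`` tie-break
makes the decomposition deterministic even under exactly tied weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

__all__ = [
    "BinaryNetwork",
    "weight_to_distance",
    "extract_orthogonal_msts",
    "global_cost_efficiency",
    "omst_threshold",
    "write_binary_network",
    "read_binary_network",
]

Edge = tuple[int, int]


@dataclass
class BinaryNetwork:
    """OMST-selected unweighted network for one subject."""

    subject_id: str
    names: list[str]
    adjacency: np.ndarray = field(repr=False)
    n_omsts_selected: int = 0
    gce_curve: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        n = len(self.names)
        if a.shape != (n, n):
            raise ValueError("adjacency shape does not match node list")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if not np.all(np.isin(a, (0, 1))):
            raise ValueError("adjacency must be binary")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        self.adjacency = a.astype(np.int8)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    def plot_gce(self, ax=None):
        """Plot the cost / GCE selection curve."""
        import matplotlib.pyplot as plt

        if self.gce_curve is None:
            raise ValueError("no GCE curve recorded")
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.gce_curve["cost"], self.gce_curve["gce"], marker="o")
        sel = self.n_omsts_selected - 1
        ax.plot(
            self.gce_curve["cost"].iloc[sel],
            self.gce_curve["gce"].iloc[sel],
            marker="*",
            markersize=14,
            color="C3",
        )
        ax.set_xlabel("cost (fraction of total similarity)")
        ax.set_ylabel("global cost efficiency")
        ax.set_title(f"{self.subject_id}: {self.n_omsts_selected} OMSTs selected")
        return ax


def weight_to_distance(weights: np.ndarray, transform: str = "reciprocal") -> np.ndarray:
    """Map similarity weights in [0, 1] to distances (monotone decreasing).

    ``reciprocal``: d = 1/w (absent where w = 0);
    ``one_minus``: d = 1 - w (absent where w = 0), for sensitivity analysis.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or np.any(w > 1):
        raise ValueError("weights must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        if transform == "reciprocal":
            d = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
        elif transform == "one_minus":
            d = np.where(w > 0, 1.0 - w, np.inf)
        else:
            raise ValueError(f"unknown distance transform {transform!r}")
    np.fill_diagonal(d, np.inf)
    return d


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def _sorted_edges(distance: np.ndarray) -> list[tuple[float, int, int]]:
    n = distance.shape[0]
    iu, ju = np.triu_indices(n, 1)
    d = distance[iu, ju]
    keep = np.isfinite(d)
    edges = list(zip(d[keep], iu[keep].tolist(), ju[keep].tolist()))
    edges.sort()  # lexicographic (distance, i, j) tie-break
    return edges


def extract_orthogonal_msts(
    distance: np.ndarray, max_rounds: int | None = None
) -> list[list[Edge]]:
    """Successive edge-disjoint minimum spanning trees (forests).

    Round m is a Kruskal MST of the graph with all edges of earlier rounds
    removed; once removal disconnects the graph, rounds are minimum spanning
    forests of the remaining components. Rounds are pairwise edge-disjoint.
    """
    distance = np.asarray(distance, dtype=float)
    n = distance.shape[0]
    if max_rounds is None:
        max_rounds = n - 1
    edges = _sorted_edges(distance)
    if not edges:
        raise ValueError("empty graph: no finite-distance edges")
    used = [False] * len(edges)
    rounds: list[list[Edge]] = []
    for _ in range(max_rounds):
        uf = _UnionFind(n)
        selected: list[int] = []
        for k, (_, i, j) in enumerate(edges):
            if used[k]:
                continue
            if uf.union(i, j):
                selected.append(k)
                if len(selected) == n - 1:
                    break
        if not selected:
            break
        for k in selected:
            used[k] = True
        rounds.append([(edges[k][1], edges[k][2]) for k in selected])
    return rounds


def _weighted_global_efficiency(
    edge_list: list[Edge], similarity: np.ndarray, transform: str = "reciprocal"
) -> float:
    n = similarity.shape[0]
    if not edge_list:
        return 0.0
    rows, cols, data = [], [], []
    for i, j in edge_list:
        w = similarity[i, j]
        d = 1.0 / w if transform == "reciprocal" else 1.0 - w
        rows += [i, j]
        cols += [j, i]
        data += [d, d]
    g = csr_matrix((data, (rows, cols)), shape=(n, n))
    D = shortest_path(g, method="D", directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def global_cost_efficiency(
    edge_list: list[Edge], similarity: np.ndarray, transform: str = "reciprocal"
) -> tuple[float, float]:
    """(cost, GCE) of a selected edge set within the similarity graph.

    cost = selected similarity mass / total similarity mass over unordered
    pairs; GCE = weighted global efficiency of the selected subgraph
    (path lengths on transformed distances, efficiency = mean reciprocal
    shortest distance) minus cost.
    """
    similarity = np.asarray(similarity, dtype=float)
    total = np.triu(similarity, 1).sum()
    if total <= 0:
        raise ValueError("similarity graph has no positive edges")
    cost = float(sum(similarity[i, j] for i, j in edge_list) / total)
    eff = _weighted_global_efficiency(edge_list, similarity, transform)
    return cost, eff - cost


def omst_threshold(
    sim,
    max_rounds: int | None = None,
    decline_patience: int = 3,
    transform: str = "reciprocal",
) -> BinaryNetwork:
    """Select the GCE-maximising cumulative OMST aggregation and binarize.

    Accepts a :class:`~ctnetwb.simnet.SimilarityMatrix` or a bare matrix.
    Evaluates GCE after each OMST round (first maximum wins on ties) and
    stops early once the curve has declined for ``decline_patience``
    consecutive rounds.
    """
    if hasattr(sim, "values") and hasattr(sim, "names"):
        subject_id, names, S = sim.subject_id, list(sim.names), np.asarray(sim.values, float)
    else:
        S = np.asarray(sim, dtype=float)
        subject_id = ""
        names = [f"node_{i}" for i in range(S.shape[0])]
    n = S.shape[0]
    pos = (S > 0).astype(int)
    n_comp, _ = connected_components(csr_matrix(pos), directed=False)
    if n_comp != 1:
        raise ValueError(
            "positive-entry similarity graph is disconnected; inspect input "
            "(too many zero/degenerate similarities)"
        )

    distance = weight_to_distance(S, transform=transform)
    if max_rounds is None:
        max_rounds = n - 1
    rounds = extract_orthogonal_msts(distance, max_rounds=max_rounds)

    cumulative: list[Edge] = []
    curve = []
    best_gce = -np.inf
    best_round = 0
    declines = 0
    prev_gce = -np.inf
    for m, rnd in enumerate(rounds, start=1):
        cumulative = cumulative + rnd
        cost, gce = global_cost_efficiency(cumulative, S, transform=transform)
        curve.append({"round": m, "n_edges": len(cumulative), "cost": cost, "gce": gce})
        if gce > best_gce:
            best_gce = gce
            best_round = m
        declines = declines + 1 if gce < prev_gce else 0
        prev_gce = gce
        if declines >= decline_patience:
            break

    selected = [e for rnd in rounds[:best_round] for e in rnd]
    A = np.zeros((n, n), dtype=np.int8)
    for i, j in selected:
        A[i, j] = A[j, i] = 1
    return BinaryNetwork(
        subject_id=subject_id,
        names=names,
        adjacency=A,
        n_omsts_selected=best_round,
        gce_curve=pd.DataFrame(curve),
    )


def write_binary_network(net: BinaryNetwork, path, curve_path=None) -> None:
    pd.DataFrame(net.adjacency, index=net.names, columns=net.names).to_csv(
        path, sep="\t"
    )
    if curve_path is not None and net.gce_curve is not None:
        net.gce_curve.to_csv(curve_path, index=False)


def read_binary_network(path, subject_id: str | None = None) -> BinaryNetwork:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if subject_id is None:
        import os

        subject_id = os.path.splitext(os.path.basename(str(path)))[0]
    a = df.to_numpy().astype(np.int8)
    return BinaryNetwork(
        subject_id=subject_id,
        names=[str(c) for c in df.columns],
        adjacency=a,
        n_omsts_selected=0,
    )
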