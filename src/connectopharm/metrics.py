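"""Global topology and node centralities of binary brain graphs.

Global measures: characteristic path length (mean geodesic over unordered
pairs), mean clustering coefficient, and Newman-Girvan modularity Q of the
best Louvain partition over restarts.  Node measures: degree, betweenness
(Brandes, unordered pairs, endpoints excluded), closeness ``(n-1)/sum d``
and eigenvector centrality normalized to maximum 1.  Betweenness is kept
unnormalized internally; the per-record table stores it divided by
``(n-1)(n-2)/2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .connectivity import BinaryGraph

__all__ = [
    "MetricsRecord",
    "path_length",
    "clustering_coefficient",
    "modularity",
    "degree",
    "betweenness",
    "closeness",
    "eigen_centrality",
    "compute_metrics",
    "NODE_METRICS",
    "GLOBAL_METRICS",
    "HUB_METRICS",
]

NODE_METRICS = ("degree", "betweenness", "closeness", "eigen_centrality")
GLOBAL_METRICS = ("path_length", "clustering", "modularity_q")
HUB_METRICS = tuple(f"hub_{m}" for m in NODE_METRICS)


def _require_connected(g: BinaryGraph, op: str) -> nx.Graph:
    G = g.to_networkx()
    if g.n_nodes >= 2 and not nx.is_connected(G):
        raise ValueError(f"{op} requires a connected graph")
    return G


def _geodesics(g: BinaryGraph, op: str) -> np.ndarray:
    """All-pairs breadth-first-search distance matrix (errors if disconnected)."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import shortest_path

    n = g.n_nodes
    if g.edges.size:
        i, j = g.edges[:, 0], g.edges[:, 1]
        a = csr_matrix(
            (np.ones(2 * len(i)), (np.r_[i, j], np.r_[j, i])), shape=(n, n)
        )
    else:
        a = csr_matrix((n, n))
    d = shortest_path(a, method="D", unweighted=True, directed=False)
    if np.isinf(d).any():
        raise ValueError(f"{op} requires a connected graph")
    return d


def path_length(g: BinaryGraph) -> float:
    """Mean shortest-path length over unordered node pairs."""
    if g.n_nodes < 2:
        raise ValueError("path_length needs at least 2 nodes")
    d = _geodesics(g, "path_length")
    iu = np.triu_indices(g.n_nodes, 1)
    return float(d[iu].mean())


def clustering_coefficient(g: BinaryGraph) -> float:
    """Mean over nodes of C_i = 2 t_i / (k_i (k_i - 1)); C_i = 0 for k_i < 2.

    Triangle counts come from the diagonal of A^3 on the dense adjacency
    matrix (node counts here are a few hundred at most).
    """
    if g.n_nodes < 3:
        raise ValueError("clustering_coefficient needs at least 3 nodes")
    a = np.zeros((g.n_nodes, g.n_nodes))
    if g.edges.size:
        a[g.edges[:, 0], g.edges[:, 1]] = 1.0
        a[g.edges[:, 1], g.edges[:, 0]] = 1.0
    triangles = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    k = a.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(k >= 2, 2.0 * triangles / (k * (k - 1.0)), 0.0)
    return float(c.mean())


def modularity(
    g: BinaryGraph, n_restarts: int = 20, seed: int = 0
) -> tuple[float, list[set[int]]]:
    """Best Louvain partition over restarts: (Q, partition).

    Q is the Newman-Girvan modularity of the highest-scoring partition among
    ``n_restarts`` Louvain runs seeded from ``seed``.
    """
    G = _require_connected(g, "modularity")
    if g.n_edges == 0:
        raise ValueError("modularity needs at least one edge")
    best_q, best_part = -np.inf, None
    for r in range(n_restarts):
        part = nx.community.louvain_communities(G, seed=seed + r)
        q = nx.community.modularity(G, part)
        if q > best_q:
            best_q, best_part = q, part
    assert best_part is not None
    return float(best_q), [set(c) for c in best_part]


def degree(g: BinaryGraph) -> np.ndarray:
    """Per-node degree (connection count)."""
    return g.degree().astype(float)


def betweenness(g: BinaryGraph, normalized: bool = False) -> np.ndarray:
    """Brandes betweenness over unordered source-target pairs, endpoints excluded."""
    bc = nx.betweenness_centrality(g.to_networkx(), normalized=normalized)
    return np.array([bc[i] for i in range(g.n_nodes)])


def closeness(g: BinaryGraph) -> np.ndarray:
    """Closeness centrality (n-1) / (sum of geodesic distances)."""
    d = _geodesics(g, "closeness")
    return (g.n_nodes - 1) / d.sum(axis=1)


def eigen_centrality(
    g: BinaryGraph, tol: float = 1e-12, max_iter: int = 10_000
) -> np.ndarray:
    """Leading adjacency eigenvector by power iteration, max-normalized to 1.

    Iterates on A + I rather than A: the shift makes the iteration matrix
    primitive for every connected graph (plain power iteration oscillates on
    bipartite graphs, e.g. trees at low density) without changing the
    eigenvector.
    """
    _require_connected(g, "eigen_centrality")
    n = g.n_nodes
    a = np.zeros((n, n))
    if g.edges.size:
        a[g.edges[:, 0], g.edges[:, 1]] = 1.0
        a[g.edges[:, 1], g.edges[:, 0]] = 1.0
    a[np.diag_indices(n)] += 1.0  # spectral shift
    v = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        w = a @ v
        w /= np.linalg.norm(w)
        if np.abs(w - v).max() < tol:
            v = w
            break
        v = w
    else:
        raise RuntimeError(
            f"eigenvector centrality did not converge in {max_iter} iterations; "
            "increase max_iter"
        )
    return v / v.max()


@dataclass
class MetricsRecord:
    """Per subject-session graph measures at one edge density.

    Node-level vectors are kept alongside the global scalars; the
    hub-averaged fields are filled by the hubs stage once a hub set exists.
    """

    subject_id: str
    session: str
    density: float
    path_length: float
    clustering: float
    modularity_q: float
    degree: np.ndarray
    betweenness: np.ndarray  # unnormalized
    closeness: np.ndarray
    eigen_centrality: np.ndarray
    hub_degree: float = np.nan
    hub_betweenness: float = np.nan
    hub_closeness: float = np.nan
    hub_eigen_centrality: float = np.nan

    def __post_init__(self) -> None:
        if not 0 <= self.clustering <= 1:
            raise ValueError(f"clustering {self.clustering} outside [0, 1]")
        if not -0.5 <= self.modularity_q <= 1:
            raise ValueError(f"modularity Q {self.modularity_q} outside [-0.5, 1]")

    @property
    def n_nodes(self) -> int:
        return len(self.degree)

    def node_metric(self, name: str) -> np.ndarray:
        if name not in NODE_METRICS:
            raise KeyError(f"unknown node metric {name!r}")
        return getattr(self, name)

    def to_row(self) -> dict:
        """Flat row for the metrics table (betweenness pair-normalized)."""
        n = self.n_nodes
        norm = (n - 1) * (n - 2) / 2 if n > 2 else 1.0
        return {
            "subject_id": self.subject_id,
            "session": self.session,
            "density": self.density,
            "path_length": self.path_length,
            "clustering": self.clustering,
            "modularity_q": self.modularity_q,
            "mean_degree": float(np.mean(self.degree)),
            "mean_betweenness": float(np.mean(self.betweenness) / norm),
            "mean_closeness": float(np.mean(self.closeness)),
            "mean_eigen_centrality": float(np.mean(self.eigen_centrality)),
            "hub_degree": self.hub_degree,
            "hub_betweenness": self.hub_betweenness / norm
            if np.isfinite(self.hub_betweenness)
            else np.nan,
            "hub_closeness": self.hub_closeness,
            "hub_eigen_centrality": self.hub_eigen_centrality,
        }


def compute_metrics(
    g: BinaryGraph,
    subject_id: str,
    session: str,
    n_restarts: int = 20,
    seed: int = 0,
    density: float | None = None,
) -> MetricsRecord:
    """All global and node metrics of one graph as a MetricsRecord.

    ``density`` labels the record (e.g. the schedule's nominal density);
    defaults to the graph's realized density.
    """
    q, _ = modularity(g, n_restarts=n_restarts, seed=seed)
    return MetricsRecord(
        subject_id=subject_id,
        session=session,
        density=g.density if density is None else density,
        path_length=path_length(g),
        clustering=clustering_coefficient(g),
        modularity_q=q,
        degree=degree(g),
        betweenness=betweenness(g),
        closeness=closeness(g),
        eigen_centrality=eigen_centrality(g),
    )
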