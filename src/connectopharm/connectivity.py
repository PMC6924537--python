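"""From per-subject BOLD time series to a binary graph at fixed edge density.

The construction chain is: trim initial volumes, high-pass filter, nuisance
regression, MODWT wavelet correlation at a chosen scale, Fisher-z transform,
then connectedness-preserving *local* thresholding to an exact target edge
density.  Local thresholding keeps every node attached through its strongest
links (a maximum spanning tree plus k-nearest-neighbour rounds) instead of
applying one global cutoff, so the graph is connected at every density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from scipy import signal

from .modwt import min_length, modwt_detail

__all__ = [
    "TimeSeriesMatrix",
    "AssociationMatrix",
    "BinaryGraph",
    "drop_initial_volumes",
    "highpass_filter",
    "regress_nuisance",
    "wavelet_correlation",
    "fisher_z",
    "coverage_exclude",
    "local_threshold",
]


# ---------------------------------------------------------------------------
# containers


def _default_labels(n: int) -> list[str]:
    return [f"node{i:03d}" for i in range(n)]


@dataclass
class TimeSeriesMatrix:
    """Node x time signal array with its sampling interval.

    ``values`` has one row per node (arbitrary BOLD units); ``tr_seconds``
    is the repetition time between volumes.
    """

    values: np.ndarray
    tr_seconds: float
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.tr_seconds <= 0:
            raise ValueError(f"tr_seconds must be > 0, got {self.tr_seconds}")
        if not self.node_labels:
            self.node_labels = _default_labels(self.n_nodes)
        if len(self.node_labels) != self.n_nodes:
            raise ValueError("node_labels length does not match number of rows")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.values.shape[1]


@dataclass
class AssociationMatrix:
    """Symmetric node x node connectivity matrix (``r`` or ``fisher_z``)."""

    values: np.ndarray
    kind: str = "r"
    scale: int | None = None
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("association matrix must be square")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("association matrix must be symmetric")
        if self.kind not in ("r", "fisher_z"):
            raise ValueError(f"kind must be 'r' or 'fisher_z', got {self.kind!r}")
        if self.kind == "r":
            off = self.values[~np.eye(self.n_nodes, dtype=bool)]
            if off.size and (np.nanmin(off) < -1 - 1e-9 or np.nanmax(off) > 1 + 1e-9):
                raise ValueError("correlations must lie in [-1, 1]")
        if not self.node_labels:
            self.node_labels = _default_labels(self.n_nodes)
        if len(self.node_labels) != self.n_nodes:
            raise ValueError("node_labels length does not match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class BinaryGraph:
    """Undirected simple graph at a fixed edge density.

    ``edges`` is an (m, 2) integer array of node-index pairs with i < j;
    ``edge_weights`` records the association strength each edge had when it
    was selected (used by the edge-list writer).
    """

    n_nodes: int
    edges: np.ndarray
    node_labels: list[str] = field(default_factory=list)
    edge_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        if self.edges.size:
            if (self.edges[:, 0] >= self.edges[:, 1]).any():
                raise ValueError("edges must satisfy i < j (no self-loops)")
            if self.edges.max() >= self.n_nodes or self.edges.min() < 0:
                raise ValueError("edge endpoint out of range")
            pairs = set(map(tuple, self.edges))
            if len(pairs) != len(self.edges):
                raise ValueError("duplicate edges")
        if not self.node_labels:
            self.node_labels = _default_labels(self.n_nodes)
        if len(self.node_labels) != self.n_nodes:
            raise ValueError("node_labels length does not match n_nodes")
        if self.edge_weights is not None:
            self.edge_weights = np.asarray(self.edge_weights, dtype=float)
            if self.edge_weights.shape[0] != self.edges.shape[0]:
                raise ValueError("edge_weights length does not match edges")

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    @property
    def density(self) -> float:
        return self.n_edges / (self.n_nodes * (self.n_nodes - 1) / 2)

    def degree(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        if self.edges.size:
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self.edges))
        return g

    def is_connected(self) -> bool:
        return self.n_nodes == 1 or nx.is_connected(self.to_networkx())


# ---------------------------------------------------------------------------
# preprocessing


def drop_initial_volumes(ts: TimeSeriesMatrix, k: int = 5) -> TimeSeriesMatrix:
    """Remove the first ``k`` volumes (magnetization-equilibration discard)."""
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    if k >= ts.n_volumes:
        raise ValueError(
            f"cannot drop {k} volumes from a series of {ts.n_volumes}"
        )
    return TimeSeriesMatrix(ts.values[:, k:], ts.tr_seconds, list(ts.node_labels))


def highpass_filter(ts: TimeSeriesMatrix, cutoff_hz: float = 0.01) -> TimeSeriesMatrix:
    """High-pass filter each node series (zero-phase Butterworth, order 2).

    Attenuates drift below ``cutoff_hz`` and removes the mean; the series
    length is preserved.
    """
    nyquist = 0.5 / ts.tr_seconds
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyquist} Hz)"
        )
    x = ts.values - ts.values.mean(axis=1, keepdims=True)
    sos = signal.butter(2, cutoff_hz, btype="highpass", fs=1.0 / ts.tr_seconds, output="sos")
    y = signal.sosfiltfilt(sos, x, axis=1)
    y = y - y.mean(axis=1, keepdims=True)
    return TimeSeriesMatrix(y, ts.tr_seconds, list(ts.node_labels))


def regress_nuisance(ts: TimeSeriesMatrix, regressors: np.ndarray) -> TimeSeriesMatrix:
    """Project out nuisance regressors (e.g. CSF signal, motion derivatives).

    An intercept is always included, so residuals are mean-free and
    orthogonal to every regressor column.  Rank-deficient designs are
    handled by the pseudo-inverse (a warning is emitted).
    """
    reg = np.atleast_2d(np.asarray(regressors, dtype=float))
    if reg.shape[0] != ts.n_volumes:
        if reg.shape[1] == ts.n_volumes:
            reg = reg.T
        else:
            raise ValueError(
                f"regressors have {reg.shape[0]} rows, expected {ts.n_volumes}"
            )
    X = np.column_stack([np.ones(ts.n_volumes), reg])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn(
            "nuisance design is rank-deficient; using pseudo-inverse",
            stacklevel=2,
        )
    beta = np.linalg.pinv(X) @ ts.values.T
    resid = ts.values.T - X @ beta
    return TimeSeriesMatrix(resid.T, ts.tr_seconds, list(ts.node_labels))


# ---------------------------------------------------------------------------
# association


def wavelet_correlation(
    ts: TimeSeriesMatrix,
    scale: int = 3,
    wavelet_name: str = "db4",
) -> AssociationMatrix:
    """Pairwise Pearson correlation of MODWT scale-``scale`` coefficients.

    Boundary-affected coefficients are discarded before correlating, so no
    wrap-around artefact couples the two ends of the scan.
    """
    need = min_length(wavelet_name, scale)
    if ts.n_volumes < need:
        raise ValueError(
            f"{ts.n_volumes} volumes too short for scale {scale} with "
            f"'{wavelet_name}': need at least {need}"
        )
    coeffs = modwt_detail(ts.values, scale, wavelet_name, discard_boundary=True)
    sd = coeffs.std(axis=1)
    if (sd == 0).any():
        bad = [ts.node_labels[i] for i in np.flatnonzero(sd == 0)[:5]]
        raise ValueError(
            f"zero-variance wavelet coefficients for nodes {bad}; mask "
            "constant nodes (coverage_exclude) before correlating"
        )
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(coeffs)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    r = (r + r.T) / 2
    return AssociationMatrix(r, kind="r", scale=scale, node_labels=list(ts.node_labels))


def n_usable_coefficients(n_volumes: int, scale: int = 3, wavelet_name: str = "db4") -> int:
    """Boundary-free coefficient count entering the wavelet correlation."""
    from .modwt import boundary_width

    return n_volumes - boundary_width(wavelet_name, scale)


def effective_df(n_volumes: int, scale: int = 3, wavelet_name: str = "db4") -> float:
    """Effective (independent-equivalent) coefficient count at a wavelet scale.

    MODWT coefficients are autocorrelated within a scale, so the usable
    sample size for a scale-``j`` correlation is the boundary-free count
    divided by ``2^j`` - the number of non-redundant (decimated) coefficients
    the band supports.  This is the quantity to use in standard errors and
    null thresholds for wavelet correlations, e.g. ``2.58 / sqrt(effective_df)``
    for a 1% two-sided null bound.
    """
    return n_usable_coefficients(n_volumes, scale, wavelet_name) / 2**scale


def fisher_z(assoc: AssociationMatrix) -> AssociationMatrix:
    """Variance-stabilizing transform z = atanh(r), elementwise off-diagonal.

    Correlations at +/-1 are clipped to +/-(1 - 1e-7) with a warning; the
    diagonal is set to 0.
    """
    if assoc.kind != "r":
        raise ValueError("fisher_z expects an r-matrix")
    r = assoc.values.copy()
    off = ~np.eye(assoc.n_nodes, dtype=bool)
    lim = 1.0 - 1e-7
    if (np.abs(r[off]) > lim).any():
        warnings.warn("|r| at or near 1 clipped before atanh", stacklevel=2)
        r[off] = np.clip(r[off], -lim, lim)
    z = np.zeros_like(r)
    z[off] = np.arctanh(r[off])
    return AssociationMatrix(
        z, kind="fisher_z", scale=assoc.scale, node_labels=list(assoc.node_labels)
    )


def coverage_exclude(coverage, min_subjects: int = 10):
    """Node keep-list after cross-subject coverage screening.

    ``coverage`` is a subject x node boolean table (True = node valid for
    that subject, i.e. non-constant and non-missing).  A node is dropped
    when it is invalid in ``min_subjects`` or more subjects; the keep-list
    is applied identically to every subject downstream.

    Returns the kept node indices (or column labels for a DataFrame).
    """
    import pandas as pd

    if isinstance(coverage, pd.DataFrame):
        labels = list(coverage.columns)
        valid = coverage.to_numpy(dtype=bool)
    else:
        valid = np.atleast_2d(np.asarray(coverage, dtype=bool))
        labels = list(range(valid.shape[1]))
    if valid.size == 0:
        raise ValueError("empty coverage table")
    n_invalid = (~valid).sum(axis=0)
    keep = n_invalid < min_subjects
    if not keep.any():
        raise ValueError("coverage screening would drop every node")
    return [lab for lab, k in zip(labels, keep) if k]


# ---------------------------------------------------------------------------
# local thresholding


def _kruskal_maximum_spanning_tree(w: np.ndarray) -> list[tuple[int, int]]:
    """Maximum spanning tree edges; ties broken by smaller node-index pair."""
    n = w.shape[0]
    iu, ju = np.triu_indices(n, 1)
    weights = w[iu, ju]
    order = np.lexsort((ju, iu, -weights))
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    tree: list[tuple[int, int]] = []
    for k in order:
        a, b = find(int(iu[k])), find(int(ju[k]))
        if a != b:
            parent[a] = b
            tree.append((int(iu[k]), int(ju[k])))
            if len(tree) == n - 1:
                break
    if len(tree) != n - 1:
        raise ValueError("association matrix yields a disconnected spanning forest")
    return tree


def local_threshold(assoc: AssociationMatrix, density: float) -> BinaryGraph:
    """Binary graph at an exact edge density via local thresholding.

    Edge strength is the absolute association value (sign-agnostic).  Stage
    one builds the maximum spanning tree, guaranteeing connectedness.  Stage
    two adds, for k = 1, 2, ..., each node's k-th strongest neighbour edge
    when absent; after the round that overshoots the target edge count
    ``m* = round(density * n(n-1)/2)``, the weakest edges added in that round
    are removed (tree edges are never removed) so exactly ``m*`` edges
    remain.  Ties are broken by weight descending then smaller node-index
    pair, making the construction deterministic.
    """
    n = assoc.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes")
    n_pairs = n * (n - 1) // 2
    if not 0 < density <= 1:
        raise ValueError(f"density must be in (0, 1], got {density}")
    m_target = int(round(density * n_pairs))
    if m_target < n - 1:
        raise ValueError(
            f"density {density} gives {m_target} edges, below the spanning-tree "
            f"minimum of {n - 1} for {n} nodes"
        )
    w = np.abs(np.asarray(assoc.values, dtype=float))
    np.fill_diagonal(w, -np.inf)

    adj = np.zeros((n, n), dtype=bool)
    chosen: dict[tuple[int, int], float] = {}
    for i, j in _kruskal_maximum_spanning_tree(w):
        adj[i, j] = adj[j, i] = True
        chosen[(i, j)] = w[i, j]

    # per-node neighbour ranking: weight descending, smaller index first
    cols = np.broadcast_to(np.arange(n), (n, n))
    order = np.lexsort((cols, -w), axis=-1)

    m = n - 1
    for k in range(n - 1):
        if m >= m_target:
            break
        partner = order[:, k]
        a = np.minimum(np.arange(n), partner)
        b = np.maximum(np.arange(n), partner)
        cand = np.unique(np.stack([a, b], axis=1), axis=0)
        new = cand[~adj[cand[:, 0], cand[:, 1]]]
        added = []
        for i, j in new:
            i, j = int(i), int(j)
            adj[i, j] = adj[j, i] = True
            chosen[(i, j)] = w[i, j]
            added.append((i, j))
        m += len(added)
        if m > m_target:
            # trim weakest of this round; ascending weight, larger pair first
            added.sort(key=lambda e: (-w[e[0], e[1]], e[0], e[1]))
            while m > m_target:
                i, j = added.pop()
                adj[i, j] = adj[j, i] = False
                del chosen[(i, j)]
                m -= 1
    if m != m_target:
        raise RuntimeError("local threshold failed to reach target density")

    edges = np.array(sorted(chosen), dtype=int).reshape(-1, 2)
    weights = np.array([chosen[tuple(e)] for e in edges])
    return BinaryGraph(
        n_nodes=n,
        edges=edges,
        node_labels=list(assoc.node_labels),
        edge_weights=weights,
    )
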