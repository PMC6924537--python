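"""Independent brute-force oracles used to validate the graph metrics.

Everything here is deliberately naive: breadth-first search and explicit
path enumeration on adjacency sets, exhaustive search over partitions for
modularity, and a permutation test for the two-sample comparison.  None of
it shares code with the implementation under test.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def bfs_distances(adj: dict[int, set[int]], source: int) -> dict[int, int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def edges_to_adj(n: int, edges) -> dict[int, set[int]]:
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for i, j in edges:
        adj[int(i)].add(int(j))
        adj[int(j)].add(int(i))
    return adj


def brute_path_length(n: int, edges) -> float:
    adj = edges_to_adj(n, edges)
    total = count = 0
    for i in range(n):
        dist = bfs_distances(adj, i)
        for j in range(i + 1, n):
            total += dist[j]
            count += 1
    return total / count


def brute_closeness(n: int, edges) -> np.ndarray:
    adj = edges_to_adj(n, edges)
    out = np.zeros(n)
    for i in range(n):
        dist = bfs_distances(adj, i)
        out[i] = (n - 1) / sum(dist[j] for j in range(n) if j != i)
    return out


def brute_clustering(n: int, edges) -> float:
    adj = edges_to_adj(n, edges)
    cs = []
    for i in range(n):
        k = len(adj[i])
        if k < 2:
            cs.append(0.0)
            continue
        t = sum(
            1
            for a, b in itertools.combinations(adj[i], 2)
            if b in adj[a]
        )
        cs.append(2 * t / (k * (k - 1)))
    return float(np.mean(cs))


def _all_shortest_paths(adj: dict[int, set[int]], s: int, t: int) -> list[tuple[int, ...]]:
    """Every geodesic from s to t, by breadth-first layer expansion."""
    dist = bfs_distances(adj, s)
    target_d = dist[t]
    paths = [(s,)]
    for d in range(target_d):
        paths = [
            p + (v,)
            for p in paths
            for v in adj[p[-1]]
            if dist.get(v) == d + 1
        ]
    return [p for p in paths if p[-1] == t]


def brute_betweenness(n: int, edges) -> np.ndarray:
    """Unnormalized betweenness over unordered pairs, endpoints excluded."""
    adj = edges_to_adj(n, edges)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = _all_shortest_paths(adj, s, t)
            for p in paths:
                for v in p[1:-1]:
                    bc[v] += 1.0 / len(paths)
    return bc


def brute_eigen_centrality(n: int, edges) -> np.ndarray:
    a = np.zeros((n, n))
    for i, j in edges:
        a[int(i), int(j)] = a[int(j), int(i)] = 1.0
    vals, vecs = np.linalg.eigh(a)
    v = np.abs(vecs[:, np.argmax(vals)])
    return v / v.max()


def _set_partitions(items: list[int]):
    """All partitions of a list into non-empty blocks."""
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def newman_girvan_q(n: int, edges, partition) -> float:
    m = len(edges)
    comm = {}
    for c, block in enumerate(partition):
        for v in block:
            comm[v] = c
    e = np.zeros(len(partition))
    d = np.zeros(len(partition))
    for i, j in edges:
        ci, cj = comm[int(i)], comm[int(j)]
        if ci == cj:
            e[ci] += 1
        d[ci] += 1
        d[cj] += 1
    return float(np.sum(e / m - (d / (2 * m)) ** 2))


def brute_best_modularity(n: int, edges) -> tuple[float, list[list[int]]]:
    """Exhaustive search over all partitions (n <= 10)."""
    best_q, best_p = -np.inf, None
    for part in _set_partitions(list(range(n))):
        q = newman_girvan_q(n, edges, part)
        if q > best_q:
            best_q, best_p = q, part
    return best_q, best_p


def permutation_ttest_p(a, b, n_perm: int = 20_000, seed: int = 0) -> float:
    """Two-sided permutation p-value for a difference in means."""
    rng = np.random.default_rng(seed)
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    observed = abs(a.mean() - b.mean())
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        count += abs(perm[: len(a)].mean() - perm[len(a):].mean()) >= observed
    return (count + 1) / (n_perm + 1)


def random_connected_graph(n: int, p: float, rng) -> list[tuple[int, int]]:
    """Random simple connected graph: random tree plus Bernoulli extra edges."""
    edges = set()
    for v in range(1, n):
        u = int(rng.integers(0, v))
        edges.add((u, v))
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) not in edges and rng.random() < p:
                edges.add((i, j))
    return sorted(edges)
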