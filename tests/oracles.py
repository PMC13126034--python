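"""Independent brute-force oracles for graph metrics.

All oracles work on a dense adjacency matrix (numpy bool, A[i, j] = directed
edge i→j) and use exhaustive enumeration — Floyd–Warshall for distances,
depth-first path enumeration for betweenness, triangle counting for clustering,
subgraph counting for the rich club.  They never call networkx, so they can
cross-check the implementation without sharing code paths.
"""

from __future__ import annotations

import numpy as np


def avg_shortest_path_undirected_lcc(adj: np.ndarray) -> float | None:
    """Mean hop distance over ordered reachable pairs in the largest connected
    component of the undirected projection; None if that component is a single
    node."""
    a = (adj | adj.T).astype(float)
    n = len(a)
    dist = np.where(a > 0, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    for k in range(n):  # Floyd–Warshall
        dist = np.minimum(dist, dist[:, k:k + 1] + dist[k:k + 1, :])
    # components from finite distances
    comps: list[list[int]] = []
    seen: set[int] = set()
    for i in range(n):
        if i in seen:
            continue
        comp = [j for j in range(n) if np.isfinite(dist[i, j])]
        seen.update(comp)
        comps.append(comp)
    comp = max(comps, key=len)
    if len(comp) < 2:
        return None
    total = sum(dist[i, j] for i in comp for j in comp if i != j)
    return total / (len(comp) * (len(comp) - 1))


def average_clustering_undirected(adj: np.ndarray) -> float:
    """Mean local clustering coefficient of the undirected projection."""
    a = (adj | adj.T)
    np.fill_diagonal(a, False)
    n = len(a)
    coeffs = []
    for v in range(n):
        nbrs = np.flatnonzero(a[v])
        k = len(nbrs)
        if k < 2:
            coeffs.append(0.0)
            continue
        links = sum(
            1 for i in range(k) for j in range(i + 1, k) if a[nbrs[i], nbrs[j]]
        )
        coeffs.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(coeffs)) if coeffs else 0.0


def _count_shortest_paths_through(adj: np.ndarray, s: int, t: int):
    """(number of shortest s→t paths, per-node counts of those passing through
    each interior node), by exhaustive depth-first enumeration."""
    n = len(adj)
    # BFS for the shortest distance
    dist = {s: 0}
    frontier = [s]
    while frontier and t not in dist:
        nxt = []
        for u in frontier:
            for v in np.flatnonzero(adj[u]):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    if t not in dist:
        return 0, np.zeros(n)
    d = dist[t]
    through = np.zeros(n)
    total = 0
    stack = [(s, [s])]
    while stack:
        u, path = stack.pop()
        if len(path) - 1 > d:
            continue
        if u == t:
            if len(path) - 1 == d:
                total += 1
                for w in path[1:-1]:
                    through[w] += 1
            continue
        for v in np.flatnonzero(adj[u]):
            if v not in path:
                stack.append((v, path + [v]))
    return total, through


def betweenness_directed(adj: np.ndarray, normalized: bool = True) -> np.ndarray:
    """Directed, unweighted betweenness by exhaustive shortest-path counting."""
    n = len(adj)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            sigma, through = _count_shortest_paths_through(adj, s, t)
            if sigma:
                bc += through / sigma
    if normalized and n > 2:
        bc /= (n - 1) * (n - 2)
    return bc


def rich_club_curve(adj: np.ndarray):
    """(thresholds, phi) for the unnormalized directed rich-club coefficient."""
    a = adj.astype(bool).copy()
    np.fill_diagonal(a, False)
    deg = a.sum(axis=0) + a.sum(axis=1)  # in + out
    ks, phis = [], []
    for k in range(0, int(deg.max()) + 1 if len(deg) else 1):
        nodes = np.flatnonzero(deg >= k)
        if len(nodes) < 2:
            break
        sub = a[np.ix_(nodes, nodes)]
        nk = len(nodes)
        ks.append(k)
        phis.append(sub.sum() / (nk * (nk - 1)))
    return ks, phis
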