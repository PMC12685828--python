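"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's own code paths (and networkx's
metric functions): shortest paths by hand-rolled BFS on an adjacency
matrix, clustering by explicit triangle counting, letter displays
verified against the pairwise significance matrix.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def bfs_distances(adj: np.ndarray, source: int) -> np.ndarray:
    n = adj.shape[0]
    dist = np.full(n, np.inf)
    dist[source] = 0
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in range(n):
            if adj[u, v] and dist[v] == np.inf:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def brute_global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    total = 0.0
    for i in range(n):
        dist = bfs_distances(adj, i)
        for j in range(n):
            if j != i and np.isfinite(dist[j]) and dist[j] > 0:
                total += 1.0 / dist[j]
    return total / (n * (n - 1))


def brute_vulnerability(adj: np.ndarray) -> float:
    e_full = brute_global_efficiency(adj)
    n = adj.shape[0]
    worst = -np.inf
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        sub = adj[np.ix_(keep, keep)]
        worst = max(worst, (e_full - brute_global_efficiency(sub)) / e_full)
    return worst


def brute_clustering(adj: np.ndarray) -> float:
    """Mean local clustering; nodes with degree < 2 contribute 0."""
    n = adj.shape[0]
    if n == 0:
        return 0.0
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            1
            for a in range(k)
            for b in range(a + 1, k)
            if adj[nbrs[a], nbrs[b]]
        )
        total += 2.0 * links / (k * (k - 1))
    return total / n


def letters_satisfy_property(
    letters: dict[str, str], pairwise_p: dict[frozenset, float], alpha: float
) -> bool:
    """Share a letter <=> pairwise test non-significant."""
    groups = list(letters)
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            share = bool(set(letters[g1]) & set(letters[g2]))
            significant = pairwise_p[frozenset((g1, g2))] < alpha
            if share == significant:
                return False
    return True


def star_robustness_expectation(n_leaves: int, p: float) -> float:
    """Exact expected remaining connectivity of a star K_{1,n} at removal
    fraction p, by enumeration over removal sets."""
    from itertools import combinations

    v = n_leaves + 1
    n_remove = int(np.floor(p * v))
    nodes = list(range(v))  # 0 = hub
    total, count = 0.0, 0
    for removed in combinations(nodes, n_remove):
        removed = set(removed)
        if 0 in removed:
            connected = 0  # every survivor is an isolated leaf
        else:
            connected = v - n_remove  # hub + leaves all keep an edge
            if n_remove == n_leaves:  # only hub left
                connected = 0 if v - n_remove == 1 else connected
        total += connected / v
        count += 1
    return total / count
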