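"""Independent brute-force oracle for graph-topology metrics.

Used by the tests only. Distances come from Floyd–Warshall; shortest-path
counts for betweenness are obtained by exhaustively enumerating all simple
paths, which is feasible for the <= 7-node graphs the oracle is applied to.
All disconnected-graph conventions mirror the definitions under test:
diameter = max over components, radius = min over components but undefined
with isolated nodes, mean distance defined only for connected graphs.
"""

from itertools import combinations

import numpy as np

INF = float("inf")


def floyd_warshall(adj):
    n = adj.shape[0]
    dist = np.full((n, n), INF)
    np.fill_diagonal(dist, 0.0)
    dist[adj != 0] = 1.0
    for k in range(n):
        dist = np.minimum(dist, dist[:, [k]] + dist[[k], :])
    return dist


def components(dist):
    n = dist.shape[0]
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        comp = {j for j in range(n) if dist[i, j] < INF}
        seen |= comp
        comps.append(sorted(comp))
    return comps


def all_simple_paths(adj, i, j):
    n = adj.shape[0]
    out = []

    def walk(node, visited, path):
        if node == j:
            out.append(list(path))
            return
        for nxt in range(n):
            if adj[node, nxt] and nxt not in visited:
                visited.add(nxt)
                path.append(nxt)
                walk(nxt, visited, path)
                path.pop()
                visited.remove(nxt)

    walk(i, {i}, [i])
    return out


def brute_metrics(adj):
    """dict with diameter, radius, mean_distance, clustering, betweenness."""
    adj = (np.asarray(adj) != 0).astype(int)
    n = adj.shape[0]
    dist = floyd_warshall(adj)
    comps = components(dist)
    diameter = max(
        max((dist[i, j] for i in c for j in c), default=0.0) for c in comps
    )
    if any(len(c) == 1 for c in comps):
        radius = None
    else:
        radius = min(
            min(max(dist[i, j] for j in c) for i in c) for c in comps
        )
    if len(comps) == 1 and n >= 2:
        mean_distance = sum(
            dist[i, j] for i in range(n) for j in range(n) if i != j
        ) / (n * (n - 1))
    else:
        mean_distance = None
    clust = 0.0
    for i in range(n):
        nbrs = np.nonzero(adj[i])[0]
        d = len(nbrs)
        if d >= 2:
            e = sum(adj[a, b] for a, b in combinations(nbrs, 2))
            clust += 2.0 * e / (d * (d - 1))
    clustering = clust / n if n else None
    betweenness = np.zeros(n)
    for i, j in combinations(range(n), 2):
        if dist[i, j] == INF:
            continue
        paths = all_simple_paths(adj, i, j)
        shortest = [p for p in paths if len(p) - 1 == dist[i, j]]
        sigma = len(shortest)
        for z in range(n):
            if z in (i, j):
                continue
            through = sum(1 for p in shortest if z in p)
            betweenness[z] += through / sigma
    return {
        "diameter": float(diameter),
        "radius": None if radius is None else float(radius),
        "mean_distance": mean_distance,
        "clustering": clustering,
        "betweenness": betweenness,
    }
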