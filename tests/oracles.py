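"""Independent brute-force oracles for graph quantities.

Everything here is written from first principles (pure-Python BFS, triple
counting, explicit shortest-path enumeration) and deliberately shares no
code with fcnet, so agreement between the two is a meaningful check.
Intended for graphs of at most ~12 nodes.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def bfs_distances(adj, source: int) -> dict[int, int]:
    n = len(adj)
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in range(n):
            if adj[u][v] and v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def all_pairs_distances(adj) -> dict[tuple[int, int], int]:
    n = len(adj)
    out = {}
    for s in range(n):
        for t, d in bfs_distances(adj, s).items():
            out[(s, t)] = d
    return out


def brute_degree(adj) -> list[int]:
    return [int(sum(row)) for row in np.asarray(adj)]


def brute_clustering(adj) -> list[float]:
    a = np.asarray(adj)
    n = a.shape[0]
    out = []
    for i in range(n):
        nb = [j for j in range(n) if a[i][j]]
        k = len(nb)
        if k < 2:
            out.append(0.0)
            continue
        links = sum(1 for u, v in itertools.combinations(nb, 2) if a[u][v])
        out.append(2.0 * links / (k * (k - 1)))
    return out


def brute_lp(adj) -> float:
    d = all_pairs_distances(adj)
    vals = [v for (s, t), v in d.items() if s != t]
    return sum(vals) / len(vals)


def brute_eg(adj) -> float:
    n = len(adj)
    if n < 2:
        return 0.0
    d = all_pairs_distances(adj)
    total = 0.0
    for s in range(n):
        for t in range(n):
            if s != t:
                total += 1.0 / d[(s, t)] if (s, t) in d else 0.0
    return total / (n * (n - 1))


def brute_ne(adj) -> list[float]:
    n = len(adj)
    out = []
    for i in range(n):
        d = bfs_distances(adj, i)
        total = sum(1.0 / d[j] for j in d if j != i)
        out.append(total / (n - 1) if n > 1 else 0.0)
    return out


def brute_eloc(adj) -> list[float]:
    a = np.asarray(adj)
    n = a.shape[0]
    out = []
    for i in range(n):
        nb = [j for j in range(n) if a[i][j]]
        if len(nb) < 2:
            out.append(0.0)
            continue
        sub = a[np.ix_(nb, nb)].tolist()
        out.append(brute_eg(sub))
    return out


def _shortest_paths(adj, s: int, t: int) -> list[tuple[int, ...]]:
    """All shortest s-t paths by depth-limited enumeration."""
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    target_len = dist[t]
    n = len(adj)
    paths = []

    def extend(path):
        u = path[-1]
        if u == t and len(path) - 1 == target_len:
            paths.append(tuple(path))
            return
        if len(path) - 1 >= target_len:
            return
        for v in range(n):
            if adj[u][v] and v not in path:
                extend(path + [v])

    extend([s])
    return paths


def brute_betweenness(adj) -> list[float]:
    """Fractional betweenness: sum over pairs (s < t) of the share of
    shortest s-t paths passing through each interior node."""
    n = len(adj)
    bc = [0.0] * n
    for s, t in itertools.combinations(range(n), 2):
        paths = _shortest_paths(adj, s, t)
        if not paths:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / len(paths)
    return bc


def brute_components(adj) -> list[set[int]]:
    n = len(adj)
    seen: set[int] = set()
    comps = []
    for s in range(n):
        if s in seen:
            continue
        comp = set(bfs_distances(adj, s))
        seen |= comp
        comps.append(comp)
    return comps


def brute_gcc(adj) -> int:
    comps = brute_components(adj)
    return max(len(c) for c in comps) if comps else 0


def replay_attack(adj, order) -> list[int]:
    """GCC after each removal in ``order`` using the brute components."""
    a = np.asarray(adj).copy()
    n = a.shape[0]
    alive = list(range(n))
    sizes = [brute_gcc(a[np.ix_(alive, alive)])]
    for node in order:
        alive.remove(node)
        if alive:
            sizes.append(brute_gcc(a[np.ix_(alive, alive)]))
        else:
            sizes.append(0)
    return sizes


def brute_pearson(x, y) -> float:
    """Textbook Pearson r: covariance over product of SDs."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / (vx**0.5 * vy**0.5)


def brute_spearman(x, y) -> float:
    """Spearman rho via mid-ranks and the Pearson formula on ranks."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    return brute_pearson(ranks(list(x)), ranks(list(y)))
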