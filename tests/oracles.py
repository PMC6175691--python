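"""Independent brute-force oracles for the graph diagnostics.

Deliberately naive: exhaustive triangle/triple counts, Floyd-Warshall
distances, exhaustive set-partition search for modularity, and a direct
Pearson correlation over edge endpoint degrees. Used only to validate the
package implementations on small graphs.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_transitivity(edges: list[tuple[int, int]], n: int) -> float:
    adj = [[False] * n for _ in range(n)]
    deg = [0] * n
    for u, v in edges:
        adj[u][v] = adj[v][u] = True
        deg[u] += 1
        deg[v] += 1
    triangles = 0
    for a, b, c in itertools.combinations(range(n), 3):
        if adj[a][b] and adj[b][c] and adj[a][c]:
            triangles += 1
    triples = sum(k * (k - 1) // 2 for k in deg)
    return 3.0 * triangles / triples if triples else 0.0


def floyd_warshall(edges: list[tuple[int, int]], n: int) -> list[list[float]]:
    d = [[math.inf] * n for _ in range(n)]
    for i in range(n):
        d[i][i] = 0.0
    for u, v in edges:
        d[u][v] = d[v][u] = 1.0
    for k in range(n):
        for i in range(n):
            dik = d[i][k]
            if dik == math.inf:
                continue
            row_k = d[k]
            row_i = d[i]
            for j in range(n):
                alt = dik + row_k[j]
                if alt < row_i[j]:
                    row_i[j] = alt
    return d


def brute_char_path_length(edges, n) -> float:
    d = floyd_warshall(edges, n)
    vals = [d[i][j] for i in range(n) for j in range(n) if i != j and math.isfinite(d[i][j])]
    if not vals:
        raise ValueError("no finite pairs")
    return sum(vals) / len(vals)


def brute_global_efficiency(edges, n) -> float:
    if n < 2:
        return 0.0
    d = floyd_warshall(edges, n)
    total = sum(
        1.0 / d[i][j]
        for i in range(n)
        for j in range(n)
        if i != j and math.isfinite(d[i][j]) and d[i][j] > 0
    )
    return total / (n * (n - 1))


def set_partitions(items: list):
    """All partitions of ``items`` (restricted-growth enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i, block in enumerate(part):
            yield part[:i] + [[first] + block] + part[i + 1 :]
        yield [[first]] + part


def modularity_of(edges, partition: list[list[int]]) -> float:
    m = len(edges)
    if m == 0:
        raise ValueError("no edges")
    label = {}
    for ci, block in enumerate(partition):
        for node in block:
            label[node] = ci
    deg: dict[int, int] = {}
    within = [0.0] * len(partition)
    for u, v in edges:
        deg[u] = deg.get(u, 0) + 1
        deg[v] = deg.get(v, 0) + 1
        if label[u] == label[v]:
            within[label[u]] += 1
    q = 0.0
    for ci, block in enumerate(partition):
        a_c = sum(deg.get(node, 0) for node in block) / (2.0 * m)
        q += within[ci] / m - a_c * a_c
    return q


def brute_max_modularity(edges, n) -> float:
    nodes = list(range(n))
    return max(modularity_of(edges, part) for part in set_partitions(nodes))


def brute_assortativity(edges, n) -> float:
    deg: dict[int, int] = {}
    for u, v in edges:
        deg[u] = deg.get(u, 0) + 1
        deg[v] = deg.get(v, 0) + 1
    xs, ys = [], []
    for u, v in edges:
        xs.extend((deg[u], deg[v]))
        ys.extend((deg[v], deg[u]))
    xs, ys = np.asarray(xs, float), np.asarray(ys, float)
    if xs.std() == 0:
        raise ValueError("degenerate")
    return float(np.corrcoef(xs, ys)[0, 1])
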