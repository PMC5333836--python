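"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's spatial-index implementations: plain
O(n^2) distance matrices, explicit loops, a local union-find and BFS.  They
replay the stated linking/ordering rules step by step so the package
implementations can be checked for exact agreement.
"""

from __future__ import annotations

import numpy as np


def brute_knn_scales(coords: np.ndarray) -> tuple[float, float, float]:
    """Average distance to the 2nd/5th/10th nearest neighbor, by full sort."""
    n = len(coords)
    assert n >= 11
    d2 = d5 = d10 = 0.0
    for i in range(n):
        diff = coords - coords[i]
        dist = np.sqrt(np.sum(diff * diff, axis=-1))
        order = np.sort(dist)
        d2 += order[2]       # order[0] is the point itself
        d5 += order[5]
        d10 += order[10]
    return d2 / n, d5 / n, d10 / n


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        self.parent[self.find(a)] = self.find(b)


def _row(coords: np.ndarray, i: int) -> np.ndarray:
    diff = coords - coords[i]
    return np.sqrt(np.sum(diff * diff, axis=-1))


def _bfs_set(adj: list[set], start: int) -> set:
    """All nodes reachable from ``start`` (including itself)."""
    seen = {start}
    queue = [start]
    while queue:
        x = queue.pop()
        for y in adj[x]:
            if y not in seen:
                seen.add(y)
                queue.append(y)
    return seen


def replay_linking(coords: np.ndarray, nn2: float, nn5: float, nn10: float):
    """Literal replay of the three linking stages.

    Returns (edges_after_stage1, edges_after_stage2, edges_after_stage3)
    as sets of sorted tuples.
    """
    n = len(coords)
    adj: list[set] = [set() for _ in range(n)]
    uf = _UnionFind(n)

    def add(i, j):
        adj[i].add(j)
        adj[j].add(i)
        uf.union(i, j)

    # stage 1: chain to nearest suitable neighbor, both degrees < 2,
    # not already connected (no path), distance < nn2
    for i in range(n):
        if len(adj[i]) >= 2:
            continue
        dist = _row(coords, i)
        best = None
        for j in range(n):
            if j == i or len(adj[j]) >= 2 or uf.find(j) == uf.find(i):
                continue
            if dist[j] < nn2 and (best is None or dist[j] < best[0]):
                best = (dist[j], j)
        if best is not None:
            add(i, best[1])
    s1 = {tuple(sorted((i, j))) for i in range(n) for j in adj[i]}

    # stage 2: loose ends to the nearest node no existing path reaches,
    # if that distance is < nn5 (BFS reachability, independent of the
    # union-find the implementation uses)
    for i in range(n):
        if len(adj[i]) > 1:
            continue
        reachable = _bfs_set(adj, i)
        dist = _row(coords, i)
        best = None
        for j in range(n):
            if j in reachable:
                continue
            if best is None or dist[j] < best[0]:
                best = (dist[j], j)
        if best is None:
            continue
        d, j = best
        if d < nn5:
            add(i, j)
    s2 = {tuple(sorted((i, j))) for i in range(n) for j in adj[i]}

    # stage 3: bridge sub-networks from degree-1 nodes, distance < nn10
    for i in range(n):
        if len(adj[i]) != 1:
            continue
        dist = _row(coords, i)
        best = None
        for j in range(n):
            if uf.find(j) == uf.find(i):
                continue
            if best is None or dist[j] < best[0]:
                best = (dist[j], j)
        if best is None:
            continue
        d, j = best
        if d < nn10:
            add(i, j)
    s3 = {tuple(sorted((i, j))) for i in range(n) for j in adj[i]}
    return s1, s2, s3


def replay_prune(n_nodes: int, edges: set) -> tuple[set, set]:
    """Naive replay of artifact pruning.

    Returns (surviving nodes, surviving edges).  Removes isolated nodes,
    spur tips with at most one intermediate node before a >=3-degree node
    (plus that intermediate), then keeps only the largest component.
    """
    adj: dict[int, set] = {i: set() for i in range(n_nodes)}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    doomed = {i for i in range(n_nodes) if not adj[i]}
    for i in range(n_nodes):
        if len(adj[i]) != 1:
            continue
        (nb,) = adj[i]
        if len(adj[nb]) >= 3:
            doomed.add(i)
        elif len(adj[nb]) == 2:
            nxt = [m for m in adj[nb] if m != i]
            if nxt and len(adj[nxt[0]]) >= 3:
                doomed.update((i, nb))
    nodes = set(range(n_nodes)) - doomed
    kept = {(a, b) for a, b in edges if a in nodes and b in nodes}
    # largest component (ties: smallest minimum node id)
    adj2: dict[int, set] = {i: set() for i in nodes}
    for a, b in kept:
        adj2[a].add(b)
        adj2[b].add(a)
    seen: set = set()
    comps = []
    for i in sorted(nodes):
        if i in seen:
            continue
        comp = {i}
        queue = [i]
        while queue:
            x = queue.pop()
            for y in adj2[x]:
                if y not in comp:
                    comp.add(y)
                    queue.append(y)
        seen |= comp
        comps.append(comp)
    comps.sort(key=lambda c: (-len(c), min(c)))
    best = comps[0] if comps else set()
    return best, {(a, b) for a, b in kept if a in best and b in best}


def recursive_strahler(children: dict[int, list[int]], root: int,
                       convention: str = "classic") -> dict[int, int]:
    """Textbook recursive Strahler definition (depth-first, no iteration)."""
    out: dict[int, int] = {}

    def visit(node: int) -> int:
        kids = children.get(node, [])
        if not kids:
            out[node] = 0
            return 0
        orders = [visit(k) for k in kids]
        m = max(orders)
        if convention == "literal":
            out[node] = m + 1
        else:
            out[node] = m + 1 if orders.count(m) >= 2 else m
        return out[node]

    visit(root)
    return out


def menger_sponge_points(level: int) -> np.ndarray:
    """Centres of the filled cells of a level-``n`` Menger sponge in [0,1]^3."""
    cells = np.array([[0, 0, 0]], dtype=float)
    size = 1.0
    for _ in range(level):
        size /= 3.0
        offsets = []
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    if ((i == 1) + (j == 1) + (k == 1)) >= 2:
                        continue
                    offsets.append((i, j, k))
        offsets = np.asarray(offsets, dtype=float) * size
        cells = (cells[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    return cells + size / 2.0
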