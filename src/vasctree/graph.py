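"""Graph reconstruction from centerline point clouds.

Centerline points become nodes of a spatial network; edges are created by a
three-stage nearest-neighbor linking protocol whose distance cutoffs adapt
to the local point density through three characteristic scales:

* ``nn2``/``nn5``/``nn10`` — the average physical distance from each point
  to its 2nd/5th/10th nearest neighbor.

Stage 1 chains points (cutoff ``nn2``, degrees capped at 2, no edge between
already-reachable nodes), stage 2 joins loose ends to the nearest node no
path already reaches (cutoff ``nn5``), and stage 3 bridges remaining
disconnected sub-networks (cutoff ``nn10``); the reachability requirements
make loop creation impossible.  Afterwards, isolated nodes,
short spurs next to bifurcations and all but the largest component are
pruned, and the surviving graph is decomposed into vessel segments —
maximal paths between nodes of degree != 2 — each carrying its length
(sum of inter-node Euclidean distances) and average diameter.

All stages iterate nodes in ascending id (file) order and break distance
ties toward the lower node id, making reconstruction deterministic for a
given input order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .centerline import CenterlineSet
from .errors import DataError

logger = logging.getLogger(__name__)

__all__ = [
    "NeighborScales",
    "VesselSegment",
    "compute_neighbor_scales",
    "build_node_graph",
    "link_stage1",
    "link_stage2",
    "link_stage3",
    "reconstruct",
    "prune_artifacts",
    "extract_segments",
    "select_root",
    "orient_from_root",
    "graph_to_edge_table",
    "export_graphml",
    "segments_to_table",
]


@dataclass(frozen=True)
class NeighborScales:
    """Characteristic nearest-neighbor distances of a point cloud (um)."""

    nn2: float
    nn5: float
    nn10: float

    def __post_init__(self) -> None:
        if not (0.0 < self.nn2 <= self.nn5 <= self.nn10):
            raise DataError(f"require 0 < nn2 <= nn5 <= nn10, got {self}")


@dataclass
class VesselSegment:
    """Maximal path between branch/terminal nodes.

    ``length`` is the sum of Euclidean inter-node distances along the path
    (um); ``diameter`` is the mean of the node diameters embedded in the
    path, endpoints included.  ``so``/``ddso`` are filled by the ordering
    stage.
    """

    index: int
    nodes: list[int]
    length: float
    diameter: float
    so: int | None = None
    ddso: int | None = None

    @property
    def endpoints(self) -> tuple[int, int]:
        return self.nodes[0], self.nodes[-1]


def compute_neighbor_scales(cs: CenterlineSet) -> NeighborScales:
    """Exact k-NN averages over all points (self excluded)."""
    n = len(cs)
    if n < 11:
        raise DataError(
            f"need >= 11 points to compute nn2/nn5/nn10 (got {n}); "
            "supply NeighborScales manually")
    tree = cKDTree(cs.coords)
    dist, _ = tree.query(cs.coords, k=11)
    # column 0 is the point itself (distance 0)
    return NeighborScales(nn2=float(dist[:, 2].mean()),
                          nn5=float(dist[:, 5].mean()),
                          nn10=float(dist[:, 10].mean()))


def build_node_graph(cs: CenterlineSet) -> nx.Graph:
    """Edge-less spatial graph: one node per centerline point.

    Node attributes: ``pos`` (um), ``diameter`` (um).  The coordinate array
    is kept on ``g.graph["coords"]`` for vectorized queries.
    """
    g = nx.Graph()
    for i, ((x, y, z), d) in enumerate(zip(cs.coords, cs.diameters)):
        g.add_node(i, pos=(float(x), float(y), float(z)), diameter=float(d))
    g.graph["coords"] = np.asarray(cs.coords, dtype=float)
    return g


def _dist(coords: np.ndarray, i: int, j) -> np.ndarray:
    diff = coords[j] - coords[i]
    return np.sqrt(np.sum(diff * diff, axis=-1))


def _add_edge(g: nx.Graph, coords: np.ndarray, i: int, j: int, stage: int) -> None:
    g.add_edge(i, j, length=float(_dist(coords, i, np.asarray(j))), stage=stage)


def link_stage1(cs: CenterlineSet, scales: NeighborScales) -> nx.Graph:
    """Stage 1: chain each node to its nearest suitable neighbor.

    Iterating nodes in ascending id order, a node ``i`` of current degree
    < 2 gains an edge to the nearest node ``j`` with current degree < 2
    that is not already connected to ``i`` (no path between them) and lies
    strictly closer than ``nn2``.  Capping both endpoints keeps every
    stage-1 degree in {0, 1, 2}; the connectivity requirement makes the
    stage loop-free, so the output is a collection of open chains.
    """
    from networkx.utils import UnionFind

    g = build_node_graph(cs)
    coords = g.graph["coords"]
    tree = cKDTree(coords)
    n = len(coords)
    uf = UnionFind(range(n))
    added = 0
    for i in range(n):
        if g.degree[i] >= 2:
            continue
        cand = tree.query_ball_point(coords[i], scales.nn2 * (1 + 1e-9))
        best = None
        for j in sorted(cand):
            if j == i or g.degree[j] >= 2 or uf[j] == uf[i]:
                continue
            d = float(_dist(coords, i, j))
            if d < scales.nn2 and (best is None or d < best[0]):
                best = (d, j)
        if best is not None:
            _add_edge(g, coords, i, best[1], stage=1)
            uf.union(i, best[1])
            added += 1
    logger.info("stage 1: %d edges", added)
    return g


def link_stage2(g: nx.Graph, scales: NeighborScales) -> nx.Graph:
    """Stage 2: attach loose ends without ever creating a loop.

    Every node of degree 0 or 1 (re-evaluated in ascending id order) is
    connected to the nearest node it cannot already reach (no existing
    path; for an undirected graph that is exactly membership in a
    different connected component, so loop creation is impossible) when
    the distance is below ``nn5``.
    """
    coords = g.graph["coords"]
    comp = {n: c for c, nodes in enumerate(nx.connected_components(g)) for n in nodes}
    labels = np.array([comp[i] for i in range(len(coords))])
    added = 0
    for i in sorted(g.nodes):
        if g.degree[i] > 1:
            continue
        other = labels != labels[i]
        if not other.any():
            continue
        idx = np.flatnonzero(other)
        dists = _dist(coords, i, idx)
        order = np.lexsort((idx, dists))
        d, j = float(dists[order[0]]), int(idx[order[0]])
        if d < scales.nn5:
            _add_edge(g, coords, i, j, stage=2)
            labels[labels == labels[j]] = labels[i]
            added += 1
    logger.info("stage 2: %d edges", added)
    return g


def link_stage3(g: nx.Graph, scales: NeighborScales) -> nx.Graph:
    """Stage 3: bridge disconnected sub-networks.

    From every degree-1 node (ascending id order, component labels refreshed
    after each accepted bridge), an edge is created to the nearest node
    belonging to a *different* sub-network when the distance is below
    ``nn10``.
    """
    coords = g.graph["coords"]
    comp = {n: c for c, nodes in enumerate(nx.connected_components(g)) for n in nodes}
    labels = np.array([comp[i] for i in range(len(coords))])
    added = 0
    for i in sorted(g.nodes):
        if g.degree[i] != 1:
            continue
        other = labels != labels[i]
        if not other.any():
            continue
        idx = np.flatnonzero(other)
        dists = _dist(coords, i, idx)
        order = np.lexsort((idx, dists))
        d, j = float(dists[order[0]]), int(idx[order[0]])
        if d < scales.nn10:
            _add_edge(g, coords, i, j, stage=3)
            labels[labels == labels[j]] = labels[i]
            added += 1
    logger.info("stage 3: %d bridges", added)
    return g


def prune_artifacts(g: nx.Graph) -> nx.Graph:
    """Remove reconstruction artifacts in a single pass.

    Removed are (a) isolated (degree-0) nodes, (b) degree-1 spur tips whose
    path to the nearest node of degree >= 3 contains at most one
    intermediate node — together with that intermediate node, so the whole
    spur disappears — and (c) every connected component except the largest.
    Degrees are evaluated on the graph as it stood before the pass
    (single pass, not iterated to a fixpoint).
    """
    to_remove = {n for n in g.nodes if g.degree[n] == 0}
    for n in g.nodes:
        if g.degree[n] != 1:
            continue
        (nb,) = g.neighbors(n)
        if g.degree[nb] >= 3:
            to_remove.add(n)  # tip attached directly to a bifurcation
        elif g.degree[nb] == 2:
            nxt = [m for m in g.neighbors(nb) if m != n]
            if nxt and g.degree[nxt[0]] >= 3:
                to_remove.update((n, nb))  # tip + one intermediate node
    g.remove_nodes_from(to_remove)
    n_spur = len(to_remove)
    if g.number_of_nodes() == 0:
        raise DataError("graph is empty after pruning")
    components = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    dropped = set().union(*components[1:]) if len(components) > 1 else set()
    g.remove_nodes_from(dropped)
    logger.info("pruning: removed %d spur/isolated nodes, %d nodes in %d minor components",
                n_spur, len(dropped), max(len(components) - 1, 0))
    if g.number_of_nodes() == 0:
        raise DataError("graph is empty after pruning")
    return g


def reconstruct(cs: CenterlineSet, scales: NeighborScales | None = None,
                prune: bool = True) -> nx.Graph:
    """Full reconstruction: scales, three linking stages, pruning."""
    if scales is None:
        scales = compute_neighbor_scales(cs)
    g = link_stage1(cs, scales)
    g = link_stage2(g, scales)
    g = link_stage3(g, scales)
    if prune:
        g = prune_artifacts(g)
    return g


def extract_segments(g: nx.Graph) -> list[VesselSegment]:
    """Decompose the graph into maximal degree-2 paths (vessel segments).

    Endpoints have degree != 2; interior nodes have degree 2.  The sum of
    segment lengths equals the sum of edge lengths exactly.  Pure cycles of
    degree-2 nodes (impossible for a tree) are skipped with a warning.
    """
    segments: list[VesselSegment] = []
    seen_edges: set[frozenset] = set()
    endpoints = sorted(n for n in g.nodes if g.degree[n] != 2)
    for start in endpoints:
        for nb in sorted(g.neighbors(start)):
            e = frozenset((start, nb))
            if e in seen_edges:
                continue
            path = [start, nb]
            seen_edges.add(e)
            while g.degree[path[-1]] == 2:
                nxt = [m for m in g.neighbors(path[-1]) if m != path[-2]][0]
                seen_edges.add(frozenset((path[-1], nxt)))
                path.append(nxt)
            segments.append(_make_segment(g, len(segments), path))
    uncovered = g.number_of_edges() - len(seen_edges)
    if uncovered:
        logger.warning("%d edges lie on pure degree-2 cycles and were skipped", uncovered)
    return segments


def _make_segment(g: nx.Graph, index: int, path: list[int]) -> VesselSegment:
    length = sum(g.edges[a, b]["length"] for a, b in zip(path, path[1:]))
    diameter = float(np.mean([g.nodes[n]["diameter"] for n in path]))
    return VesselSegment(index=index, nodes=path, length=float(length), diameter=diameter)


def select_root(g: nx.Graph) -> int:
    """Injection-inlet heuristic: the degree-1 node with the largest diameter.

    Diameter ties break toward the lower node id.  Overridable by passing an
    explicit root downstream.
    """
    tips = [n for n in g.nodes if g.degree[n] == 1]
    if not tips:
        raise DataError("graph has no degree-1 node to serve as root")
    return min(tips, key=lambda n: (-g.nodes[n]["diameter"], n))


def orient_from_root(g: nx.Graph, root: int) -> nx.DiGraph:
    """Directed copy with edges oriented from the root toward the terminals."""
    if root not in g:
        raise DataError(f"root node {root} not in graph")
    dg = nx.DiGraph()
    dg.add_nodes_from(g.nodes(data=True))
    for parent, child in nx.bfs_edges(g, root):
        dg.add_edge(parent, child, **g.edges[parent, child])
    dg.graph.update(g.graph)
    dg.graph["root"] = root
    return dg


def graph_to_edge_table(g: nx.Graph):
    """Edge list as a DataFrame (node ids, coordinates, diameters, length)."""
    import pandas as pd

    rows = []
    for a, b, data in g.edges(data=True):
        pa, pb = g.nodes[a]["pos"], g.nodes[b]["pos"]
        rows.append({
            "node_a": a, "node_b": b,
            "xa": pa[0], "ya": pa[1], "za": pa[2],
            "xb": pb[0], "yb": pb[1], "zb": pb[2],
            "diameter_a": g.nodes[a]["diameter"], "diameter_b": g.nodes[b]["diameter"],
            "length": data["length"],
        })
    return pd.DataFrame(rows)


def export_graphml(g: nx.Graph, path: str | Path) -> Path:
    """Write the graph as GraphML (positions flattened to x/y/z attributes)."""
    h = nx.Graph() if not g.is_directed() else nx.DiGraph()
    for n, data in g.nodes(data=True):
        x, y, z = data["pos"]
        h.add_node(n, x=float(x), y=float(y), z=float(z),
                   diameter=float(data["diameter"]))
    for a, b, data in g.edges(data=True):
        h.add_edge(a, b, length=float(data["length"]))
    nx.write_graphml(h, str(path))
    return Path(path)


def segments_to_table(segments: list[VesselSegment]):
    """Segments as a DataFrame: id, endpoints, length, diameter, SO, DDSO."""
    import pandas as pd

    return pd.DataFrame([
        {"segment": s.index, "node_a": s.endpoints[0], "node_b": s.endpoints[1],
         "n_nodes": len(s.nodes), "length": s.length, "diameter": s.diameter,
         "so": s.so, "ddso": s.ddso}
        for s in segments
    ])
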