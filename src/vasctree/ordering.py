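"""Strahler and diameter-defined Strahler ordering of vessel segments.

Strahler ordering (SO) ranks segments from the terminals toward the root:
terminal segments get order 0 and orders grow at confluences.  Two parent
rules are available:

* ``classic`` (default) — the standard Strahler rule: the parent order is
  the maximum of the daughter orders, incremented by one only when that
  maximum is attained by two or more daughters;
* ``literal`` — the parent is always one order above the largest daughter
  order, which turns the order into the bifurcation depth from the
  terminals.

Because vessels of comparable caliber can end up in different Strahler
orders, the diameter-defined refinement (DDSO, after Kassab's scheme for
the coronary arterial tree) iterates two steps to a fixpoint: compute the
mean ``D_n`` and SD ``Delta_n`` of segment diameters per order, then
reassign each segment ``k`` to the order ``n`` whose diameter interval

    ( (D_{n-1} + Delta_{n-1}) + (D_n - Delta_n) ) / 2
        <  D_k  <=
    ( (D_n + Delta_n) + (D_{n+1} - Delta_{n+1}) ) / 2

contains its diameter (missing neighbor terms at the boundary orders are
-inf/+inf).  Segments matching no interval keep their current order for
that iteration; interval boundaries assign to the lower order.  Final
orders are relabeled contiguously from 0 in ascending mean diameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import DataError
from .graph import VesselSegment

logger = logging.getLogger(__name__)

__all__ = [
    "assign_strahler",
    "strahler_orders",
    "assign_ddso",
    "DdsoResult",
    "OrderStatistics",
    "order_statistics",
]


def _segment_tree(segments: list[VesselSegment], graph: nx.Graph,
                  root: int) -> tuple[list[int], dict[int, list[int]]]:
    """Orient segments away from the root; return (bfs order, children map).

    Each segment's node path is re-ordered proximal -> distal (root to
    terminal); reversing a path gives the terminal-to-root direction.
    """
    if root not in graph:
        raise DataError(f"root node {root} not in graph")
    if graph.number_of_edges() != graph.number_of_nodes() - 1 or not nx.is_connected(graph):
        raise DataError("Strahler ordering requires a connected acyclic graph (tree)")
    by_endpoint: dict[int, list[int]] = {}
    for s in segments:
        for e in set(s.endpoints):
            by_endpoint.setdefault(e, []).append(s.index)
    if root not in by_endpoint:
        raise DataError(f"root node {root} is not a segment endpoint")
    seg_of = {s.index: s for s in segments}
    children: dict[int, list[int]] = {s.index: [] for s in segments}
    order: list[int] = []
    visited_nodes = {root}
    visited_segs: set[int] = set()
    frontier = [(root, si) for si in sorted(by_endpoint[root])]
    while frontier:
        node, si = frontier.pop(0)
        if si in visited_segs:
            continue
        visited_segs.add(si)
        s = seg_of[si]
        if s.nodes[0] != node:
            s.nodes.reverse()
        order.append(si)
        distal = s.nodes[-1]
        visited_nodes.add(distal)
        for child in sorted(by_endpoint.get(distal, [])):
            if child not in visited_segs:
                children[si].append(child)
                frontier.append((distal, child))
    if len(visited_segs) != len(segments):
        raise DataError("segment adjacency is not a single tree")
    return order, children


def strahler_orders(children: dict[int, list[int]], bfs_order: list[int],
                    convention: str = "classic") -> dict[int, int]:
    """Order assignment on an abstract (children-map) segment tree."""
    if convention not in ("classic", "literal"):
        raise DataError(f"unknown Strahler convention {convention!r}")
    so: dict[int, int] = {}
    for si in reversed(bfs_order):
        kids = children[si]
        if not kids:
            so[si] = 0
        else:
            orders = [so[k] for k in kids]
            m = max(orders)
            if convention == "literal":
                so[si] = m + 1
            else:
                so[si] = m + 1 if orders.count(m) >= 2 else m
    return so


def assign_strahler(segments: list[VesselSegment], graph: nx.Graph, root: int,
                    convention: str = "classic") -> list[VesselSegment]:
    """Assign Strahler orders from the terminals toward the root.

    Terminal segments (the root inlet excluded) receive order 0.  Junctions
    of more than two daughters (trifurcations) are treated as coincident
    bifurcations: the parent rule is evaluated over all daughters.
    """
    bfs_order, children = _segment_tree(segments, graph, root)
    so = strahler_orders(children, bfs_order, convention)
    for s in segments:
        s.so = so[s.index]
    return segments


@dataclass
class DdsoResult:
    converged: bool
    n_iterations: int
    n_orders: int


def _order_stats(diameters: np.ndarray, orders: np.ndarray,
                 ddof: int) -> tuple[np.ndarray, np.ndarray]:
    m = orders.max() + 1
    means = np.empty(m)
    sds = np.empty(m)
    for n in range(m):
        d = diameters[orders == n]
        means[n] = d.mean()
        sds[n] = d.std(ddof=ddof) if len(d) > ddof else 0.0
    return means, sds


def ddso_intervals(means: np.ndarray, sds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-order diameter intervals ``(lower, upper]`` of the DDSO criterion."""
    m = len(means)
    lower = np.full(m, -np.inf)
    upper = np.full(m, np.inf)
    for n in range(m):
        if n > 0:
            lower[n] = ((means[n - 1] + sds[n - 1]) + (means[n] - sds[n])) / 2.0
        if n < m - 1:
            upper[n] = ((means[n] + sds[n]) + (means[n + 1] - sds[n + 1])) / 2.0
    return lower, upper


def _compress(orders: np.ndarray) -> np.ndarray:
    """Relabel order values contiguously from 0, preserving their ranking."""
    uniq = np.unique(orders)
    remap = {int(v): i for i, v in enumerate(uniq)}
    return np.array([remap[int(v)] for v in orders], dtype=int)


def assign_ddso(segments: list[VesselSegment], max_iter: int = 100,
                sd_ddof: int = 1) -> tuple[list[VesselSegment], DdsoResult]:
    """Iterate the diameter-defined reassignment to a fixpoint.

    ``sd_ddof=1`` uses the sample SD (default); 0 the population SD.
    Non-convergence within ``max_iter`` returns the last state with
    ``converged=False``.  Final orders are contiguous from 0 with strictly
    non-decreasing (and, after merging, strictly increasing) mean diameter.
    """
    if not segments:
        raise DataError("no segments to order")
    if any(s.so is None for s in segments):
        raise DataError("Strahler orders must be assigned before DDSO")
    diameters = np.array([s.diameter for s in segments], dtype=float)
    orders = _compress(np.array([s.so for s in segments], dtype=int))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        means, sds = _order_stats(diameters, orders, sd_ddof)
        lower, upper = ddso_intervals(means, sds)
        new = orders.copy()
        for k, dk in enumerate(diameters):
            hit = np.flatnonzero((lower < dk) & (dk <= upper))
            if len(hit):
                new[k] = hit[0]  # boundary/overlap ties go to the lower order
        new = _compress(new)
        if np.array_equal(new, orders):
            converged = True
            break
        orders = new
    if not converged:
        logger.warning("DDSO did not converge within %d iterations", max_iter)
    # relabel by ascending mean diameter so order rank follows caliber
    means, _ = _order_stats(diameters, orders, sd_ddof)
    rank = np.argsort(means, kind="stable")
    remap = np.empty_like(rank)
    remap[rank] = np.arange(len(rank))
    orders = remap[orders]
    for s, o in zip(segments, orders):
        s.ddso = int(o)
    result = DdsoResult(converged=converged, n_iterations=it,
                        n_orders=int(orders.max()) + 1)
    logger.info("DDSO: %d orders after %d iterations (converged=%s)",
                result.n_orders, it, converged)
    return segments, result


@dataclass
class OrderStatistics:
    """Per-order summary table.

    Columns: ``order``, ``count``, ``diameter_mean`` (D_n, um),
    ``diameter_sd`` (Delta_n, um), ``length_mean`` (um), and — once
    :func:`vasctree.metrics.resistance_per_order` has run — ``resistance``.
    """

    table: "object"  # pandas DataFrame
    order_attr: str = "ddso"

    def __len__(self) -> int:
        return len(self.table)


def order_statistics(segments: list[VesselSegment], order_attr: str = "ddso",
                     sd_ddof: int = 1) -> OrderStatistics:
    """Exact per-order mean/SD of diameters, mean length and segment count."""
    import pandas as pd

    values = [getattr(s, order_attr) for s in segments]
    if any(v is None for v in values):
        raise DataError(f"{order_attr} not assigned on all segments")
    orders = np.asarray(values, dtype=int)
    uniq = np.unique(orders)
    if uniq[0] != 0 or not np.array_equal(uniq, np.arange(len(uniq))):
        raise DataError(f"{order_attr} orders must be contiguous from 0, got {uniq}")
    diameters = np.array([s.diameter for s in segments])
    lengths = np.array([s.length for s in segments])
    rows = []
    for n in uniq:
        sel = orders == n
        d = diameters[sel]
        rows.append({
            "order": int(n),
            "count": int(sel.sum()),
            "diameter_mean": float(d.mean()),
            "diameter_sd": float(d.std(ddof=sd_ddof)) if sel.sum() > sd_ddof else 0.0,
            "length_mean": float(lengths[sel].mean()),
        })
    return OrderStatistics(table=pd.DataFrame(rows), order_attr=order_attr)
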