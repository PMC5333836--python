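"""Global, distributional and morphofunctional vascular metrics.

* Box-counting fractal dimension ``D_f`` of the centerline point cloud:
  cover the cloud with grid boxes of edge ``x`` anchored at the bounding-box
  minimum; the occupied-box count follows ``N(x) ~ x**-D_f`` and ``D_f`` is
  the negative slope of the least-squares line through ``(ln x, ln N)``.
* Totals: overall centerline length ``l = sum(l_k)`` and cylinder-sum
  volume ``V = sum(pi * l_k * (D_k / 2)**2)`` over all vessel segments.
* Absolute and relative frequency distributions of segment diameters and
  lengths with half-open bins ``[v, v + dv)``; relative histograms are
  normalized per sample by its segment count, then averaged across the
  samples of a group (samples weighted equally, not segments).
* Per-order Hagen-Poiseuille resistance estimate
  ``R = <l> / (n * <D>**4)`` in arbitrary units (viscosity and the
  ``128/pi`` constant deliberately dropped — the estimate is proportional,
  not absolute).
* Bifurcation angles from the scalar product of the two daughter direction
  vectors at each branch node — invariant to global translation/rotation.
* Terminal shortest distances ``d_min`` — for each terminal point the
  Euclidean distance to its nearest other terminal; their mean and variance
  summarize the density and homogeneity of the pre-capillary bed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats as sstats
from scipy.spatial import cKDTree

from .centerline import CenterlineSet
from .errors import DataError
from .graph import VesselSegment
from .ordering import OrderStatistics

logger = logging.getLogger(__name__)

__all__ = [
    "FractalResult",
    "box_counts",
    "default_box_ladder",
    "fractal_dimension",
    "total_length",
    "total_volume",
    "DistributionSet",
    "distributions",
    "resistance_per_order",
    "bifurcation_angles",
    "AngleSummary",
    "terminal_distances",
    "TerminalDistanceSummary",
    "MetricsReport",
]


# ---------------------------------------------------------------------------
# fractal dimension


@dataclass
class FractalResult:
    box_sizes: np.ndarray      # um
    counts: np.ndarray
    d_f: float
    fit_range: tuple[int, int]  # slice [start, stop) of the ladder used
    r_squared: float


def _as_points(points) -> np.ndarray:
    if isinstance(points, CenterlineSet):
        return points.coords
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 3:
        raise DataError(f"points must be (n, 3), got {pts.shape}")
    return pts


def box_counts(points, box_sizes) -> np.ndarray:
    """Occupied-box counts for each box edge, grid anchored at the bbox minimum."""
    pts = _as_points(points)
    lo = pts.min(axis=0)
    counts = []
    for x in box_sizes:
        # 1e-9 box-units guard: points an ulp below a box boundary must not
        # spill into the lower box (matters for exactly gridded inputs)
        idx = np.floor((pts - lo) / float(x) + 1e-9).astype(np.int64)
        counts.append(len(np.unique(idx, axis=0)))
    return np.asarray(counts)


def default_box_ladder(points, spacing: float | None = None,
                       factor: float = 2.0) -> np.ndarray:
    """Geometric box-size ladder from ``2 * spacing`` to 1/4 of the bbox edge.

    Without a known spacing, the smallest inter-point scale is estimated
    from the nearest-neighbor distance of a subsample.
    """
    pts = _as_points(points)
    extent = float(np.max(pts.max(axis=0) - pts.min(axis=0)))
    if extent <= 0:
        raise DataError("degenerate point cloud: zero spatial extent")
    if spacing is None:
        sub = pts[:: max(1, len(pts) // 2000)]
        d, _ = cKDTree(pts).query(sub, k=2)
        spacing = float(np.median(d[:, 1]))
    x0 = 2.0 * spacing
    x1 = extent / 4.0
    if x1 <= x0:
        raise DataError("bounding box too small for the default box ladder")
    n = int(math.floor(math.log(x1 / x0, factor))) + 1
    return x0 * factor ** np.arange(max(n, 4))


def fractal_dimension(points, ladder=None, spacing: float | None = None,
                      fit_range: tuple[int, int] | None = None) -> FractalResult:
    """Box-counting fractal dimension of a point cloud.

    ``ladder`` is the sequence of box edges (um); by default a factor-2
    geometric ladder over the scaling region.  ``fit_range`` restricts the
    log-log fit to ladder indices ``[start, stop)``; ``r_squared`` is
    reported so users can judge and narrow the scaling range.
    """
    pts = _as_points(points)
    if len(np.unique(pts, axis=0)) < 2:
        raise DataError("fractal dimension requires >= 2 distinct points")
    ladder = default_box_ladder(pts, spacing=spacing) if ladder is None \
        else np.asarray(ladder, dtype=float)
    if len(ladder) < 4:
        raise DataError("box ladder must contain >= 4 sizes")
    order = np.argsort(ladder)
    ladder = ladder[order]
    counts = box_counts(pts, ladder)
    fit_range = (0, len(ladder)) if fit_range is None else fit_range
    sl = slice(*fit_range)
    x, y = np.log(ladder[sl]), np.log(counts[sl])
    if len(x) < 2:
        raise DataError("fit_range must cover >= 2 ladder points")
    res = sstats.linregress(x, y)
    d_f = -float(res.slope)
    if not (0.0 < d_f <= 3.0 + 1e-6):
        logger.warning("fitted D_f=%.3f outside (0, 3]; check the box ladder", d_f)
    return FractalResult(box_sizes=ladder, counts=counts, d_f=d_f,
                         fit_range=tuple(fit_range),
                         r_squared=float(res.rvalue) ** 2)


# ---------------------------------------------------------------------------
# totals


def total_length(segments: list[VesselSegment]) -> float:
    """Overall centerline length ``l`` (um)."""
    return float(sum(s.length for s in segments))


def total_volume(segments: list[VesselSegment]) -> float:
    """Cylinder-sum vessel volume ``V`` (um^3)."""
    return float(sum(math.pi * s.length * (s.diameter / 2.0) ** 2 for s in segments))


# ---------------------------------------------------------------------------
# distributions


@dataclass
class DistributionSet:
    """Absolute and relative histograms of segment diameters and lengths.

    ``diameter``/``length`` are DataFrames with columns ``bin_left``,
    ``N`` (group-mean absolute count) and ``P`` (group-mean per-sample
    relative frequency).  With a single sample ``P`` sums to 1.
    """

    dD: float
    dl: float
    diameter: "object"
    length: "object"
    n_samples: int


def _histogram(values: np.ndarray, width: float) -> dict[int, int]:
    idx = np.floor(values / width).astype(int)
    return dict(zip(*np.unique(idx, return_counts=True)))


def distributions(samples, dD: float = 10.0, dl: float = 50.0) -> DistributionSet:
    """Histogram segment diameters and lengths with half-open bins.

    ``samples`` is either one segment list (single sample) or a list of
    segment lists (one per sample of a phenotype group).  Absolute counts
    ``N`` and per-sample-normalized relative frequencies ``P`` are averaged
    across samples on the union of occupied bins (missing bins count 0), so
    every sample carries equal weight regardless of its segment count.
    """
    import pandas as pd

    if dD <= 0 or dl <= 0:
        raise DataError("bin widths dD and dl must be > 0")
    if samples and isinstance(samples[0], VesselSegment):
        samples = [samples]
    if not samples or any(not s for s in samples):
        raise DataError("each sample must contain at least one segment")

    def build(width: float, attr: str):
        hists = [_histogram(np.array([getattr(s, attr) for s in sample]), width)
                 for sample in samples]
        bins = sorted(set().union(*hists))
        rows = []
        for b in bins:
            ns = [h.get(b, 0) for h in hists]
            ps = [h.get(b, 0) / sum(h.values()) for h in hists]
            rows.append({"bin_left": b * width, "N": float(np.mean(ns)),
                         "P": float(np.mean(ps))})
        return pd.DataFrame(rows)

    return DistributionSet(dD=dD, dl=dl,
                           diameter=build(dD, "diameter"),
                           length=build(dl, "length"),
                           n_samples=len(samples))


# ---------------------------------------------------------------------------
# resistance


def resistance_per_order(stats: OrderStatistics) -> OrderStatistics:
    """Append the per-order resistance estimate ``R = <l> / (n * <D>**4)``.

    Arbitrary units: blood viscosity and the absolute Poiseuille constant
    are dropped, keeping the estimate proportional across orders.
    """
    table = stats.table
    if (table["diameter_mean"] <= 0).any():
        raise DataError("resistance undefined for zero mean diameter")
    table = table.copy()
    table["resistance"] = table["length_mean"] / (
        table["count"] * table["diameter_mean"] ** 4)
    return OrderStatistics(table=table, order_attr=stats.order_attr)


# ---------------------------------------------------------------------------
# bifurcation angles


@dataclass
class AngleSummary:
    angles: np.ndarray         # degrees
    mean: float
    sd: float
    per_order: "object"        # DataFrame (order, count, mean, sd) or None


def _daughter_vector(dg: nx.DiGraph, branch: int, daughter: int,
                     lookahead) -> np.ndarray:
    """Direction vector from the branch node toward a daughter.

    ``lookahead`` is the number of path nodes to walk into the daughter
    branch (1 = immediate neighbor), or ``"segment"`` for the daughter
    segment's distal endpoint (the next node of out-degree != 1).
    """
    pos = np.asarray(dg.nodes[branch]["pos"])
    node, prev = daughter, branch
    steps = 0
    while True:
        steps += 1
        succ = list(dg.successors(node))
        if lookahead == "segment":
            if len(succ) != 1:
                break
        elif steps >= int(lookahead):
            break
        elif len(succ) != 1:
            break
        prev, node = node, succ[0]
    return np.asarray(dg.nodes[node]["pos"]) - pos


def bifurcation_angles(dg: nx.DiGraph, segments: list[VesselSegment] | None = None,
                       lookahead=1) -> AngleSummary:
    """Angles between daughter direction vectors at every branch node.

    For each pair of daughters at a branch node, the angle is
    ``arccos(r_i . r_j / (|r_i| |r_j|))`` with the vectors anchored at the
    branch node — independent of the absolute position and orientation of
    the network.  Zero-length vectors are skipped with a log message.
    When ordered ``segments`` are given, each angle is attributed to the
    DDSO of the parent segment ending at the branch node, and a per-order
    summary is included.
    """
    import pandas as pd

    seg_order: dict[int, int] = {}
    if segments is not None:
        for s in segments:
            if s.ddso is not None:
                seg_order[s.nodes[-1]] = s.ddso  # distal endpoint = branch node
    angles, orders = [], []
    for node in sorted(dg.nodes):
        daughters = sorted(dg.successors(node))
        if len(daughters) < 2:
            continue
        for i in range(len(daughters)):
            for j in range(i + 1, len(daughters)):
                ri = _daughter_vector(dg, node, daughters[i], lookahead)
                rj = _daughter_vector(dg, node, daughters[j], lookahead)
                ni, nj = np.linalg.norm(ri), np.linalg.norm(rj)
                if ni == 0 or nj == 0:
                    logger.warning("zero-length daughter vector at node %d; pair skipped", node)
                    continue
                cosang = np.clip(np.dot(ri, rj) / (ni * nj), -1.0, 1.0)
                angles.append(math.degrees(math.acos(cosang)))
                orders.append(seg_order.get(node))
    angles = np.asarray(angles)
    per_order = None
    if segments is not None and len(angles):
        rows = []
        arr_orders = np.array([-1 if o is None else o for o in orders])
        for o in sorted(set(arr_orders[arr_orders >= 0])):
            a = angles[arr_orders == o]
            rows.append({"order": int(o), "count": len(a),
                         "angle_mean": float(a.mean()),
                         "angle_sd": float(a.std(ddof=1)) if len(a) > 1 else 0.0})
        per_order = pd.DataFrame(rows)
    mean = float(angles.mean()) if len(angles) else float("nan")
    sd = float(angles.std(ddof=1)) if len(angles) > 1 else 0.0
    return AngleSummary(angles=angles, mean=mean, sd=sd, per_order=per_order)


# ---------------------------------------------------------------------------
# terminal distances


@dataclass
class TerminalDistanceSummary:
    distances: np.ndarray  # um, one per terminal
    mean: float
    sd: float
    variance: float


def terminal_distances(dg: nx.DiGraph) -> TerminalDistanceSummary:
    """Shortest distance from each terminal point to its nearest other terminal.

    Terminals are the leaves of the directed tree (the root/injection inlet
    is not a leaf and is thus excluded).  The variance of ``d_min``
    quantifies the homogeneity of the terminal bed.
    """
    leaves = [n for n in dg.nodes if dg.out_degree(n) == 0]
    if len(leaves) < 2:
        raise DataError("need >= 2 terminals to compute d_min")
    pos = np.array([dg.nodes[n]["pos"] for n in leaves])
    d, _ = cKDTree(pos).query(pos, k=2)
    dmin = d[:, 1]
    return TerminalDistanceSummary(
        distances=dmin, mean=float(dmin.mean()),
        sd=float(dmin.std(ddof=1)) if len(dmin) > 1 else 0.0,
        variance=float(dmin.var(ddof=1)) if len(dmin) > 1 else 0.0)


# ---------------------------------------------------------------------------
# report


@dataclass
class MetricsReport:
    """Bundle of all computed metrics for one sample."""

    n_segments: int
    total_length: float
    total_volume: float
    fractal: FractalResult
    order_stats: OrderStatistics
    angle_summary: AngleSummary
    terminal_summary: TerminalDistanceSummary
    distribution_set: DistributionSet
    meta: dict = field(default_factory=dict)

    def scalar_dict(self) -> dict:
        """Flat scalar view (used for group averaging and JSON export)."""
        return {
            "n_segments": self.n_segments,
            "total_length": self.total_length,
            "total_volume": self.total_volume,
            "fractal_dimension": self.fractal.d_f,
            "fractal_fit_r2": self.fractal.r_squared,
            "n_ddso": len(self.order_stats),
            "max_ddso": len(self.order_stats) - 1,
            "angle_mean": self.angle_summary.mean,
            "angle_sd": self.angle_summary.sd,
            "dmin_mean": self.terminal_summary.mean,
            "dmin_sd": self.terminal_summary.sd,
            "dmin_variance": self.terminal_summary.variance,
        }

    def to_json_dict(self) -> dict:
        return {
            "scalars": self.scalar_dict(),
            "order_statistics": self.order_stats.table.to_dict(orient="records"),
            "angle_per_order": (self.angle_summary.per_order.to_dict(orient="records")
                                if self.angle_summary.per_order is not None else None),
            "box_counting": {
                "box_sizes": self.fractal.box_sizes.tolist(),
                "counts": self.fractal.counts.tolist(),
                "fit_range": list(self.fractal.fit_range),
            },
            "meta": self.meta,
        }
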