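"""Parametric synthetic vascular trees with exact ground truth.

The generator builds strictly bifurcating (optionally trifurcating) 3D trees
with straight cylindrical segments, Murray-law diameter tapering
(``d_parent^3 = sum d_daughter^3``), a fixed inter-daughter branching angle
(90 degrees by default, matching the branching geometry of real arterial
networks), and per-generation length scaling.  Every derived quantity the
pipeline later measures — segment lengths and diameters, Strahler orders,
totals, tip positions, branch angles — is known in closed form and exported
as :class:`GroundTruth`.

Three views of the same tree are produced:

* the analytic geometry (:func:`generate_tree`),
* a jittered/subsampled centerline point cloud (:func:`tree_to_centerline`)
  emulating skeletonization output,
* a voxelized Hounsfield-unit volume (:func:`voxelize_tree`) with additive
  noise and interior cavities emulating inhomogeneous contrast filling.

All randomness is driven by the spec seed; the same seed reproduces
bit-identical outputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .centerline import CenterlineSet
from .errors import ConfigError, DataError
from .volume import BinaryMask, VoxelVolume

logger = logging.getLogger(__name__)

__all__ = [
    "TreeSpec",
    "TreeSegment",
    "SyntheticTree",
    "GroundTruth",
    "generate_tree",
    "tree_to_centerline",
    "rasterize_tree",
    "voxelize_tree",
]

_GOLDEN_ANGLE = math.radians(137.50776405003785)


@dataclass
class TreeSpec:
    """Parameters of the synthetic arterial tree.

    Defaults are chosen to emulate the arterial tree of a small organ imaged
    at 16 um: a ~240 um root artery bifurcating over five generations down
    to ~95 um pre-terminal arterioles, which yields five distinct diameter
    levels and hence five diameter-defined Strahler orders.
    """

    depth: int = 5                    # branching generations (segments = 2^depth - 1)
    branching_angle: float = 90.0     # angle between daughters, degrees
    length_ratio: float = 0.85        # daughter/parent length factor
    taper_exponent: float = 3.0       # Murray exponent; daughters = parent * 2**(-1/exp)
    root_diameter: float = 240.0      # um
    root_length: float = 960.0        # um
    jitter_sd: float = 2.0            # centerline positional jitter, um
    dropout_fraction: float = 0.0     # random centerline point removal
    cavity_rate: float = 0.5          # interior cavities per 1000 foreground voxels
    daughters: int = 2                # 3 = trifurcating robustness variant
    tilt: tuple = (8.0, 12.0)         # root tilt about x/y (degrees) vs the grid
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ConfigError("depth must be >= 1")
        if not (0.0 < self.length_ratio <= 1.0):
            raise ConfigError("length_ratio must be in (0, 1]")
        if not (0.0 <= self.dropout_fraction < 1.0):
            raise ConfigError("dropout_fraction must be in [0, 1)")
        if self.root_diameter <= 0 or self.root_length <= 0:
            raise ConfigError("root_diameter and root_length must be > 0")
        if self.taper_exponent <= 0:
            raise ConfigError("taper_exponent must be > 0")
        if self.daughters not in (2, 3):
            raise ConfigError("daughters must be 2 or 3")

    @property
    def taper_factor(self) -> float:
        """Per-generation diameter factor from the symmetric Murray rule."""
        return self.daughters ** (-1.0 / self.taper_exponent)


@dataclass
class TreeSegment:
    """One straight vessel segment of the analytic tree."""

    index: int
    parent: int            # -1 for the root segment
    generation: int        # 0 at the root
    start: np.ndarray
    end: np.ndarray
    diameter: float

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end - self.start))

    @property
    def direction(self) -> np.ndarray:
        d = self.end - self.start
        return d / np.linalg.norm(d)


@dataclass
class SyntheticTree:
    segments: list[TreeSegment]
    spec: TreeSpec

    def __len__(self) -> int:
        return len(self.segments)

    def children(self, index: int) -> list[int]:
        return [s.index for s in self.segments if s.parent == index]


@dataclass
class GroundTruth:
    """Exact per-segment table and analytic summaries of a generated tree."""

    segments: "object"        # pandas DataFrame: index, parent, generation, length, diameter, so
    total_length: float       # um
    total_volume: float       # um^3 (cylinder sum)
    tip_positions: np.ndarray
    branch_angles: np.ndarray  # degrees, one per internal branch point pair
    n_segments: int
    max_so: int
    n_diameter_levels: int

    def to_json_dict(self) -> dict:
        return {
            "n_segments": self.n_segments,
            "total_length": self.total_length,
            "total_volume": self.total_volume,
            "max_so": self.max_so,
            "n_diameter_levels": self.n_diameter_levels,
            "mean_branch_angle": float(np.mean(self.branch_angles)) if len(self.branch_angles) else None,
        }


def _perpendicular(d: np.ndarray, azimuth: float) -> np.ndarray:
    """Unit vector perpendicular to ``d`` at the given azimuth about it."""
    ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u0 = ref - np.dot(ref, d) * d
    u0 /= np.linalg.norm(u0)
    v0 = np.cross(d, u0)
    return math.cos(azimuth) * u0 + math.sin(azimuth) * v0


def generate_tree(spec: TreeSpec) -> tuple[SyntheticTree, GroundTruth]:
    """Build the analytic tree and its exact ground truth.

    The construction is fully deterministic: branching planes rotate by the
    golden angle from one branch point to the next so that deep trees do not
    self-intersect, daughters leave the branch point symmetrically at
    ``branching_angle / 2`` from the parent direction, diameters follow the
    symmetric Murray rule and lengths shrink by ``length_ratio`` per
    generation.  The whole tree is tilted by ``spec.tilt`` relative to the
    voxel-grid axes — scanned organs never align with the scanner frame,
    and an exactly grid-aligned vessel is a degenerate configuration for
    thinning algorithms.
    """
    import pandas as pd

    tx, ty = (math.radians(a) for a in spec.tilt)
    rot_x = np.array([[1, 0, 0],
                      [0, math.cos(tx), -math.sin(tx)],
                      [0, math.sin(tx), math.cos(tx)]])
    rot_y = np.array([[math.cos(ty), 0, math.sin(ty)],
                      [0, 1, 0],
                      [-math.sin(ty), 0, math.cos(ty)]])
    root_dir = rot_y @ rot_x @ np.array([0.0, 0.0, 1.0])
    half = math.radians(spec.branching_angle) / 2.0
    segments: list[TreeSegment] = [
        TreeSegment(0, -1, 0, np.zeros(3), spec.root_length * root_dir,
                    spec.root_diameter)
    ]
    frontier = [0]
    for gen in range(1, spec.depth):
        next_frontier = []
        length = spec.root_length * spec.length_ratio ** gen
        diameter = spec.root_diameter * spec.taper_factor ** gen
        for parent_idx in frontier:
            parent = segments[parent_idx]
            d = parent.direction
            u = _perpendicular(d, _GOLDEN_ANGLE * parent_idx)
            if spec.daughters == 2:
                directions = [math.cos(half) * d + math.sin(half) * u,
                              math.cos(half) * d - math.sin(half) * u]
            else:
                v = np.cross(d, u)
                directions = []
                for k in range(3):
                    az = 2.0 * math.pi * k / 3.0
                    w = math.cos(az) * u + math.sin(az) * v
                    directions.append(math.cos(half) * d + math.sin(half) * w)
            for dd in directions:
                dd = dd / np.linalg.norm(dd)
                idx = len(segments)
                segments.append(TreeSegment(idx, parent_idx, gen, parent.end.copy(),
                                            parent.end + length * dd, diameter))
                next_frontier.append(idx)
        frontier = next_frontier
    tree = SyntheticTree(segments, spec)

    # classic Strahler orders, bottom-up
    so = np.zeros(len(segments), dtype=int)
    children: dict[int, list[int]] = {s.index: [] for s in segments}
    for s in segments:
        if s.parent >= 0:
            children[s.parent].append(s.index)
    for s in sorted(segments, key=lambda s: -s.generation):
        kids = children[s.index]
        if kids:
            orders = [so[k] for k in kids]
            m = max(orders)
            so[s.index] = m + 1 if orders.count(m) >= 2 else m
    df = pd.DataFrame({
        "index": [s.index for s in segments],
        "parent": [s.parent for s in segments],
        "generation": [s.generation for s in segments],
        "length": [s.length for s in segments],
        "diameter": [s.diameter for s in segments],
        "so": so,
    })
    lengths = df["length"].to_numpy()
    diams = df["diameter"].to_numpy()
    total_length = float(lengths.sum())
    total_volume = float(np.sum(math.pi * lengths * (diams / 2.0) ** 2))
    tips = np.array([s.end for s in segments if not children[s.index]])
    angles = []
    for s in segments:
        kids = children[s.index]
        for i in range(len(kids)):
            for j in range(i + 1, len(kids)):
                di = segments[kids[i]].direction
                dj = segments[kids[j]].direction
                angles.append(math.degrees(math.acos(np.clip(np.dot(di, dj), -1, 1))))
    gt = GroundTruth(
        segments=df,
        total_length=total_length,
        total_volume=total_volume,
        tip_positions=tips,
        branch_angles=np.asarray(angles),
        n_segments=len(segments),
        max_so=int(so.max()),
        n_diameter_levels=int(len(np.unique(np.round(diams, 9)))),
    )
    return tree, gt


def tree_to_centerline(tree: SyntheticTree, step: float = 16.0,
                       jitter_sd: float | None = None,
                       dropout_fraction: float | None = None,
                       seed: int | None = None) -> CenterlineSet:
    """Sample centerline points along every segment at the given step (um).

    Each segment contributes its distal endpoint plus interior samples every
    ``step`` um measured back from the distal end; the root segment also
    contributes the inlet point.  Junction points are therefore sampled
    exactly once.  Gaussian positional jitter and Bernoulli point dropout
    emulate voxelization noise and imperfect skeleton coverage.
    """
    if step <= 0:
        raise ConfigError("step must be > 0")
    spec = tree.spec
    jitter_sd = spec.jitter_sd if jitter_sd is None else jitter_sd
    dropout_fraction = spec.dropout_fraction if dropout_fraction is None else dropout_fraction
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    coords, diams = [], []
    for s in tree.segments:
        length = s.length
        ts = np.arange(length, 0.0, -step)
        ts = ts[ts > 1e-9 * length][::-1]  # ascending, ends at length; guard
        # against a float-epsilon sample duplicating the proximal junction
        if s.parent < 0:
            ts = np.concatenate(([0.0], ts))
        pts = s.start + np.outer(ts / length, s.end - s.start)
        coords.append(pts)
        diams.append(np.full(len(pts), s.diameter))
    coords = np.concatenate(coords)
    diams = np.concatenate(diams)
    if jitter_sd > 0:
        coords = coords + rng.normal(0.0, jitter_sd, coords.shape)
    if dropout_fraction > 0:
        keep = rng.random(len(coords)) >= dropout_fraction
        coords, diams = coords[keep], diams[keep]
    return CenterlineSet(coords, diams, meta={"sample": "synthetic", "spacing": step})


def rasterize_tree(tree: SyntheticTree, spacing: float = 16.0,
                   margin: int = 3) -> BinaryMask:
    """Exact union-of-capsules occupancy of the tree on a voxel grid.

    A voxel is foreground iff its centre lies within one segment radius of
    the segment axis (spherical caps included, which keeps junctions
    water-tight).  The grid origin is placed so that the tree plus a margin
    of ``margin`` voxels fits.
    """
    if spacing <= 0:
        raise ConfigError("spacing must be > 0")
    min_d = min(s.diameter for s in tree.segments)
    if min_d < spacing:
        raise DataError(
            f"smallest segment diameter {min_d:.1f} um is below one voxel "
            f"({spacing} um); increase root_diameter/taper or reduce depth")
    pts = np.array([p for s in tree.segments for p in (s.start, s.end)])
    rmax = max(s.diameter for s in tree.segments) / 2.0
    raw_lo = pts.min(axis=0) - rmax - margin * spacing
    # Anchor the grid to the voxel lattice with a fixed fractional offset
    # relative to the tree's coordinate frame: a perfectly grid-aligned
    # vessel axis lying exactly between voxel centres is a degenerate
    # symmetric configuration (parallel thinning can annihilate it) that
    # real scans never produce.  Snapping makes the offset deterministic
    # for every tree, whatever its bounding box.
    lo = spacing * (np.floor(raw_lo / spacing) - np.array([0.29, 0.37, 0.43]))
    hi = pts.max(axis=0) + rmax + margin * spacing
    shape = tuple(int(math.ceil((hi[a] - lo[a]) / spacing)) + 1 for a in range(3))
    n_vox = int(np.prod(shape))
    if n_vox > 4e8:
        raise DataError(f"voxel grid {shape} exceeds the configured maximum")
    occ = np.zeros(shape, dtype=bool)
    for s in tree.segments:
        r = s.diameter / 2.0
        smin = np.minimum(s.start, s.end) - r - spacing
        smax = np.maximum(s.start, s.end) + r + spacing
        i0 = np.maximum(np.floor((smin - lo) / spacing).astype(int), 0)
        i1 = np.minimum(np.ceil((smax - lo) / spacing).astype(int) + 1, shape)
        ax = [lo[a] + spacing * np.arange(i0[a], i1[a]) for a in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        p = np.stack([gx, gy, gz], axis=-1)
        ab = s.end - s.start
        denom = float(np.dot(ab, ab))
        t = np.clip(np.tensordot(p - s.start, ab, axes=([-1], [0])) / denom, 0.0, 1.0)
        closest = s.start + t[..., None] * ab
        dist2 = np.sum((p - closest) ** 2, axis=-1)
        occ[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= dist2 <= r * r
    return BinaryMask(occ, spacing=(spacing,) * 3, origin=tuple(lo))


def voxelize_tree(tree: SyntheticTree, spacing: float = 16.0,
                  foreground_hu: float = 3000.0, background_hu: float = 0.0,
                  noise_sd: float = 200.0, cavity_rate: float | None = None,
                  seed: int | None = None, margin: int = 3) -> VoxelVolume:
    """Render the tree as a Hounsfield-unit volume.

    Additive Gaussian noise emulates detector noise; a fraction of interior
    foreground voxels (``cavity_rate`` per 1000 foreground voxels) is
    flipped to background to emulate inhomogeneous contrast-agent filling,
    which downstream morphological closing is expected to repair.
    """
    from scipy import ndimage

    spec = tree.spec
    cavity_rate = spec.cavity_rate if cavity_rate is None else cavity_rate
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    mask = rasterize_tree(tree, spacing=spacing, margin=margin)
    occ = mask.data.copy()
    n_fg = int(occ.sum())
    if cavity_rate > 0 and n_fg:
        struct = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
        interior = ndimage.binary_erosion(occ, structure=struct, border_value=0)
        cand = np.argwhere(interior)
        n_cav = min(len(cand), int(round(cavity_rate * n_fg / 1000.0)))
        if n_cav:
            sel = cand[rng.choice(len(cand), size=n_cav, replace=False)]
            occ[sel[:, 0], sel[:, 1], sel[:, 2]] = False
            logger.info("flipped %d interior voxels to background (cavities)", n_cav)
    hu = np.full(occ.shape, background_hu, dtype=float)
    hu[occ] = foreground_hu
    if noise_sd > 0:
        hu += rng.normal(0.0, noise_sd, hu.shape)
    return VoxelVolume(hu, spacing=mask.spacing, origin=mask.origin)
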