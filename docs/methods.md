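# Methods

This note records the models, conventions and numerical choices behind
`vasctree`, in the order the pipeline applies them, together with what the
synthetic test bed does and does not establish about real data.

## Segmentation

A vessel voxel is foreground iff its attenuation lies in the user's window
`[hu_low, hu_high]`. There are deliberately no default bounds: the window
depends on contrast agent and scanner calibration and is chosen per study
(`suggest_threshold` logs an Otsu-based starting point but never applies
it). Morphological closing uses a ball of radius 1 voxel by default; the
mask is padded by the element radius first, so closing never erodes
original foreground, and the operation is idempotent. 26-connectivity
defines components (filter default: 50 voxels, configurable) and skeleton
adjacency; the 6-neighborhood defines surface voxels, with out-of-array
space counting as background.

Skeletonization is topology-preserving 3D medial-axis thinning
(Lee's algorithm as implemented in scikit-image). The contract is the
post-condition — a ≤ 2-voxel-wide, 26-connected skeleton with the mask's
component count — not the specific thinning; `skeletonize_mask` warns if
thinning ever changes the component count. One genuine failure mode of
parallel thinning is worth knowing: a cylinder whose axis is exactly
grid-aligned *and* lies exactly between voxel centres in both transverse
axes is perfectly symmetric under the directional sub-iterations and can be
annihilated entirely. Real scans never produce this configuration (organs
are not aligned with the scanner frame); the synthetic generator avoids it
explicitly (see below).

### Radius estimation

For a skeleton voxel, `s_min` is the Euclidean (physical-unit) distance to
the nearest surface voxel. All surface voxels within
`radius_factor * s_min` (default 1.5) form the inspection neighborhood, and
their nearest distances to the skeleton are averaged. The enlarged
neighborhood compensates for surface roughness that makes the bare `s_min`
an underestimate on non-circular discrete cross-sections.

Two sub-voxel corrections are applied by default, both standard practice in
skeleton-based morphometry and both exposed as parameters:

* **Partial-volume offset** (`surface_offset`, default 0.5 voxel): surface
  voxel *centres* sit on average about half a voxel inside the physical
  vessel interface, so the raw averaged distance underestimates the radius
  by ≈ spacing/2. The offset is added once to the averaged distance. On
  digital cylinders of radius 3–15 voxels the corrected estimate recovers
  the true radius to within ~0.1 voxel away from end effects; without the
  offset the estimate sits half a voxel low, which biases the cylinder-sum
  volume V by ≈ −20% at the calibers of a 16 µm kidney scan.
* **Skeleton recentering** (`recenter`, default on): each skeleton voxel is
  moved to the centre of mass of foreground within 1.5× its inscribed
  radius (the same adaptive multiplier as the radius neighborhood). Raw
  26-connected voxel paths overestimate length by the staircase factor —
  up to +13% at generic 3D orientations when inter-node Euclidean steps are
  summed — and recentering pulls the path onto the continuous axis,
  reducing the total-length error on voxelized test trees from ≈ +11% to
  ≈ ±1%. Exported centerline coordinates are therefore physical µm and not
  necessarily voxel centres.

## Graph reconstruction

The characteristic scales nn2/nn5/nn10 are exact k-NN averages over the raw
points, computed once before any linking (they are not recomputed after
edits). All three stages iterate nodes in ascending input order and break
distance ties toward the lower node id, making reconstruction deterministic
for a given file.

* **Stage 1** (cutoff nn2): a node of current degree < 2 is linked to its
  nearest neighbor that also has degree < 2 and is *not already reachable*
  from it. Reading "not already connected" as graph connectivity (enforced
  with a union-find) rather than as the mere absence of a direct edge is a
  deliberate design choice: with the direct-edge reading, three mutually
  close points (routine near junctions and under jitter) close triangles,
  and those loops survive to the final network, where a tree is required
  for ordering. Capping both endpoints keeps all stage-1 degrees in
  {0, 1, 2}, so the stage emits open chains.
* **Stage 2** (cutoff nn5): every node of degree ≤ 1 is joined to the
  nearest node *no existing path reaches*. For an undirected graph,
  path-nonexistence is exactly membership in another connected component,
  so the reachability requirement doubles as a loop-prevention guarantee.
  The "nearest unreachable" formulation is again deliberate: a chain end's
  literal nearest node is its own predecessor, under which the stage would
  connect nothing.
* **Stage 3** (cutoff nn10): from every degree-1 node, a bridge to the
  nearest node of a different sub-network, with component labels refreshed
  after each accepted bridge. Degree-0 nodes are not bridge sources; any
  still isolated after stage 2 are artifacts and fall to pruning.

Pruning is a single pass over the degrees as they stood after linking:
isolated nodes go; a degree-1 tip whose path to the nearest node of degree
≥ 3 has at most one intermediate node goes together with that intermediate
(the whole spur); then only the largest component is kept. The pass is not
iterated to a fixpoint — longer spurs are treated as real terminal
branches, which they usually are.

Vessel segments are maximal paths whose interior nodes have degree 2.
`D_k` averages the diameters of all nodes on the path, endpoints included;
junction nodes are thus shared between the segments meeting there. Root
selection (the injection inlet) defaults to the degree-1 node with the
largest diameter and can be overridden.

## Ordering

Two Strahler parent rules ship behind `convention`:

* `classic` (default): parent = max(daughter orders), incremented only when
  the maximum is attained at least twice — the standard stream-order
  definition, verified against an independent recursive oracle.
* `literal`: parent = max(daughter orders) + 1 at every junction, which
  makes the order the bifurcation depth from the terminals. It is kept
  because descriptions of terminal-upward order propagation are sometimes
  meant this way; the two coincide on perfectly balanced trees.

Junctions with more than two daughters are treated as coincident
bifurcations: the parent rule runs over all daughters, and angles are
computed for every daughter pair.

The DDSO iteration alternates per-order statistics (sample SD by default,
`sd_ddof=0` for population SD; singleton orders have SD 0) with interval
reassignment. Boundary orders take −∞/+∞ for the missing neighbor terms. A
segment whose diameter falls in no interval — possible when intervals
invert under large SDs — keeps its current order for that iteration; a
diameter on an interval boundary goes to the lower order, and when
overlapping intervals both contain a diameter the lowest matching order
wins (ascending scan). Orders are compressed to a contiguous 0..m−1 after
every iteration, and on convergence (fixpoint of the assignment, or
`max_iter` = 100 with a logged warning) relabeled by ascending mean
diameter, so order rank always follows caliber. The number of DDSO levels
is a *result* of the diameter distribution, not a parameter.

## Metrics

* **Box counting**: grids are anchored at the point cloud's bounding-box
  minimum. The default ladder is geometric with factor 2 from 2× the point
  spacing to ¼ of the largest bounding-box edge; `r²` of the log-log fit is
  reported so users can restrict `fit_range` to the scaling region.
  Occupied-box counts are guaranteed non-increasing only for *nested*
  ladders (each size an integer multiple of the previous, as the default
  is); for arbitrary size pairs the anchored-grid count can fluctuate
  slightly. A 10⁻⁹ box-unit epsilon keeps exactly gridded points from
  spilling across box boundaries.
* **Totals**: V uses the cylinder approximation per segment; on tapering
  vessels this overestimates relative to a frustum sum by O(taper²) per
  segment, which for Murray-tapered trees sampled at segment resolution is
  under 2%.
* **Distributions**: half-open bins `[v, v + dv)` anchored at 0 (defaults
  dD = 10 µm, dl = 50 µm); relative histograms are normalized by each
  sample's segment count and then averaged across the samples of a group on
  the union of occupied bins (absent bins count 0) — each sample carries
  equal weight regardless of its size.
* **Resistance**: R = ⟨l⟩/(n⟨D⟩⁴) in arbitrary units; blood viscosity and
  the 128/π constant are deliberately dropped, keeping the estimate
  proportional across orders rather than absolute.
* **Angles**: vectors run from the branch node to the `lookahead`-th node
  into each daughter (default 1 = immediate neighbor) or, with
  `lookahead="segment"`, to the daughter segment's distal endpoint. At
  skeleton resolution the immediate-neighbor vectors are quantized to the
  26 lattice directions and can sit a node away from the anatomical
  junction, so endpoint vectors are the faithful measure of inter-branch
  geometry; nearest-neighbor vectors probe the local lattice geometry
  instead. Angles are invariant to global translation and rotation.
  Each angle is attributed to the DDSO of the parent segment ending at the
  branch node.
* **Terminal distances**: `d_min` uses the leaves of the rooted, directed
  tree (the inlet is never a leaf); the variance of `d_min` is the
  homogeneity summary.

## Synthetic test bed

`TreeSpec` builds strictly bifurcating (optionally trifurcating) trees:
root 240 µm diameter and 960 µm length, five generations, symmetric Murray
taper (daughter = parent · 2^(−1/3), so a depth-d tree tips at
root · 2^(−(d−1)/3)), length ratio 0.85, inter-daughter angle 90°,
branching planes rotated by the golden angle per junction so deep trees do
not self-intersect. These defaults emulate a small-organ arterial tree
imaged at 16 µm — tip vessels of ~95 µm (≈ 3 voxel radius) and exactly five
distinct diameter levels, hence five DDSO levels. The whole tree is tilted
(8°, 12°) against the grid axes and the rasterizer anchors its voxel grid
at a fixed fractional offset: scanned organs never align with the scanner
frame, and the tilt keeps the generator away from the degenerate
grid-aligned thinning configuration described above.

Centerline sampling emits one point per 16 µm (the voxel pitch) with
Gaussian positional jitter of 2 µm SD, emulating sub-voxel skeleton error.
Jitter is i.i.d. per point, which is *harsher* than real voxelization error
at equal amplitude: beyond ≈ 0.15× the sampling step it starts to swap the
order of points along a vessel, something on-grid skeletons never do, and
reconstruction then fragments chains. Dropout and interior cavities
(per-1000-foreground-voxel rate, exercising the closing operator) are off
and 0.5 by default. Voxelization is an exact union-of-capsules test at
voxel centres with additive Gaussian HU noise (SD 200 against a 3000 HU
foreground).

What passing the synthetic suite does show: the chain from voxels to
ordered metrics is self-consistent and recovers known geometry (segment
count exactly, totals to a few percent, angles to ~1°, radii to ~0.2 voxel
away from tips) at realistic caliber-to-voxel ratios. What it does not
show: robustness to anastomoses (loops are out of scope — the method
targets arterial trees), to strongly inhomogeneous contrast filling beyond
single-voxel cavities, to beam hardening or reconstruction artifacts, or to
vessels at or below one voxel in diameter, where thinning and radius
estimation both degrade.

## Degenerate inputs and errors

Empty threshold results warn and propagate an empty-mask error only when
the final mask is empty; a mask whose only components fall below the size
cutoff warns. Fewer than 11 centerline points cannot support the k-NN
scales and require manual nn2/nn5/nn10. Graphs with cycles are rejected by
the ordering stage. Fewer than two terminals make `d_min` undefined
(error). Single-point or coincident point clouds are rejected by the
fractal estimator, as are ladders with fewer than four sizes.

## Known limitations

* Length measurements inherit whatever staircase residue recentering does
  not remove (≈ 1% on test trees); diameter accuracy is bounded by the
  half-voxel surface quantization the offset corrects only on average.
* The DDSO fixpoint is not unique in pathological diameter distributions;
  the ascending-scan tie-break makes the implementation deterministic but
  other valid fixpoints exist.
* Group distribution averaging assumes commensurate bin grids across
  samples (same dD/dl); mixed voxel spacings within a group are flagged,
  not resolved.
* The resistance estimate ignores viscosity, non-Newtonian effects and
  pulsatility by design; it ranks orders, it does not predict pressures.
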