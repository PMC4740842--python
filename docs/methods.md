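# Methods

This note records the geometric model behind `guideforge`, the parameters
that matter, the numerical choices, and what the synthetic fixtures do and
do not demonstrate.

## Problem setting and assumptions

The input is a triangulated anatomy surface in millimetres (STL from CT or
CBCT reconstruction), assumed *connected* and *manifold* in the region of
interest: the segmentation walks mesh edges and splits the vertex graph, so
non-manifold input is rejected at read time and holes near the border loop
are out of scope (no hole patching is attempted). STL carries no
connectivity, so vertices coincident within 1e-6 mm are welded on read;
that tolerance sits above float32 STL quantisation noise and below any
anatomical feature. Indices are 0-based, the frame right-handed, and face
winding CCW seen from outside wherever the surface is orientable.

## Inner surface: segmentation by a signed scalar field

The user's border is a closed loop of ≥3 control points near the surface.
Because batch use has no camera, the interactive screen-space projection of
a GUI is replaced by geometric closest-point snapping (point-to-triangle
minimisation, KD-pruned and exact); snapping farther than `max_snap`
(default 10 mm) is treated as a units/frame error rather than silently
accepted. The loop is interpolated with a closed cardinal spline of tension
0.5 (Catmull–Rom — the tension is otherwise unconstrained and 0.5 is the
common default), resampled at `densify_step` (default 1 mm) with the first
sample of each spline segment kept at the control point, and re-snapped.
Closed loops whose chained segments come within 1e-9 mm of each other are
rejected as self-intersecting.

Edge-loop tracking snaps each loop point to its closest mesh vertex and
greedily walks neighbors: from the current vertex the next one must lie
within 90° of the anchor-to-anchor direction (dot ≥ 0) and minimise the
perpendicular distance to the anchor line, ties breaking toward the smaller
vertex index for determinism. When no neighbor qualifies, or after 200
steps, the walk falls back to a Dijkstra shortest path over mesh edges with
Euclidean weights. Revisit detours are pruned so the cycle is simple; a
cycle that breaks adjacency is an error.

Every vertex's unsigned scalar is the minimum distance over the loop's
segments, computed with explicit per-component arithmetic so a scalar
re-implementation reproduces it bit for bit (asserted in the tests).
Removing the edge-loop vertices must split the vertex graph into ≥2
components; the component nearest a caller hint point is positive. Which
side is "positive" is genuinely a user decision (the pipeline defaults the
hint to the mesh vertex nearest the control-loop centroid, i.e. the region
enclosed by the loop). Edge-loop vertices are signed from their
largest-scalar off-loop neighbor `N` by comparing `|NP|` against `|NQ|`
(`Q` the closest polyline point): if `P` is closer to `N` than the polyline
is, they are on the same side.

Clipping treats exact-zero scalars as positive — deterministic, and
consistent with the interpolation parameter `t = |s_a| / (|s_a| + |s_b|)`
reaching its `t = 0` endpoint. Zero crossings are deduplicated by
unordered edge key so the cut boundary is a single crack-free polyline;
splitting a mixed triangle into three conserves area to machine precision.

## Offset and outer surfaces

The offset surface is the iso-distance set of the inner surface, extracted
by sampling the unsigned distance field on a regular grid over the inner
surface's bounding box expanded by `padding` (default 2× thickness) at
`voxel` resolution (default thickness/4) and contouring with the standard
marching-cubes case table (linear interpolation, scikit-image's reference
implementation). Grid node values are exact point-to-triangle minima — the
KD pruning uses the nearest-vertex distance plus the largest triangle
circumradius as a search radius, which provably never discards the closest
triangle — so the only offset error is the contouring one: every offset
vertex lies within one voxel of the nominal thickness, and halving the
voxel halves that bound (first-order convergence, checked on the sphere
fixture). A grid larger than 2×10⁷ nodes or an isosurface touching the
grid boundary is an error, not a silent truncation. Direct
triangle/vertex-normal offsetting is deliberately not used: the outer face
only needs the general trend of the anatomy, and normal offsets tear or
self-intersect in concave regions.

The outer surface is clipped out of the closed offset with the same
signed-scalar machinery. The clipping loop comes from the inner border:
every `sampling_step`-th ordered boundary point (default 10) is projected
along the average of its normal and its `normal_window` (default 5)
nearest boundary neighbors' normals — the averaging keeps the projected
loop from self-intersecting where the border wiggles. The boundary is
ordered before subsampling (the stitcher needs the order anyway). A ray
that misses the offset falls back to the closest point (logged). Side
selection is a ray cast from the inner vertex farthest from the border
along its outward normal; the first offset hit seeds the positive side.
Note the clipped outer border consists of interpolated zero-crossing
vertices on offset-mesh edges, so its vertex count is governed by the
offset tessellation, not by the projected sample count.

## Ruled side wall

The side wall between the inner border (`m` points) and outer border (`n`
points) is a triangle strip: each triangle is one contour segment plus two
spans `P_iQ_j`, and the non-crossing condition makes the span sequence
monotone, so open-mode stitching always emits exactly m + n − 2 triangles.
The minimal-total-span strip is the shortest monotone path in the directed
span grid, computed by a two-phase label setting (row 0 and column 0 first,
then a double loop comparing the two predecessors under strict `<`, ties
taking the left predecessor) — on this DAG it coincides with Dijkstra,
asserted exactly over random loop pairs. Loop alignment rotates `q` so the
point nearest `P_0` becomes `Q_0` (ties to the smaller index); winding
consistency is checked by the sign of the loops' areas projected on their
common best-fit plane, with an opt-in auto-reverse. Closed mode adds two
seam triangles over the wrap segments `P_{m-1}P_0` and `Q_{n-1}Q_0`, split
along the shorter seam diagonal, so the welded inner + outer + wall shell
is watertight; open mode is kept for the exact m + n − 2 count.

## Drilling tubes and union merging

A drilling tube is a watertight annular cylinder: outer wall, bore wall
with reversed winding, two annulus caps, 32 circumferential segments by
default, and the walls subdivided into roughly isotropic axial rings so a
boolean cut removes only a narrow band of triangles. Callers position the
tube to straddle the shell.

Only the union flavour of booleans is needed, which allows a simplified
merge. Collision detection builds covariance-fitted OBB trees (median
split on the longest box axis, leaf size 4) and tests the surviving
triangle pairs with an edge-based routine — each edge of one triangle
against the other's bounding box, plane and barycentric interior — run
symmetrically in both directions, because one direction alone cannot
recover both endpoints of a transversal intersection segment in all
configurations. Coplanar overlapping pairs (normal alignment within 1e-8)
fall back to pairwise edge–edge intersection points. The OBB-pruned result
is asserted identical to an all-pairs scan on every fixture.

Per-pair segments are chained into polylines by endpoint matching at
1e-7 mm; open chains indicate tangential contact and abort the merge.
Marked triangles are removed, the remaining faces split into edge-connected
fragments, and a fragment is kept iff a sample point on it (centroid of its
largest face) lies outside the other closed mesh by ray parity. Each kept
fragment's ragged boundary is matched to a polyline by mean closest
distance plus a perimeter-similarity term — proximity alone cannot
separate concentric cut circles on a thin shell — and sealed with a closed
ruled seam. Two deliberate robustness rules handle cuts smaller than the
local tessellation: a fragment bounded by a single cut circle and no larger
than ~1.5× its disk is a remnant of the erased surface and is dropped; and
any polyline left with fewer than two seams is capped with a centroid fan
so the union still closes. Closure of every polyline from both sides, plus
the strip's edge bookkeeping, makes the union of closed inputs closed —
checked, with the boundary edges reported on failure.

The final template is re-oriented consistently (BFS edge-direction
propagation, globally flipped to positive signed volume) so its volume is
meaningful.

## Synthetic fixtures and what the tests show

No clinical meshes ship with the package. The fixtures are an icosphere
(closed, analytically checkable: radii, areas, radial normals, hemisphere
areas), a sinusoidal ridge height field (open, gentle relief standing in
for a jaw or vertebra patch), and a seeded demo plan (rectangle-ish
eight-point loop over the mesh middle, drill axes along local normals,
radii 1.25/2.5 mm — drill-guide scale). All fixtures are deterministic
given their parameters and seed; the design algorithms themselves are
RNG-free, so identical inputs give bit-identical STL output.

These fixtures exercise every code path at desk scale (10³–10⁵ elements;
the complexity check uses 10⁴–4×10⁴-vertex ridges, sizes chosen so the
linear-cost term dominates fixed overheads). They do not reproduce
clinical mesh pathologies — scan noise, slivers, holes near the border,
partially edentulous "shortcut" undercuts — so passing tests demonstrate
algorithmic correctness on clean manifold geometry, not robustness to
defective reconstructions.

## Known limitations

- Segmentation requires a connected mesh; holes near the contour can break
  loop generation, and no hole patching is attempted.
- Undercut ("shortcut") detection — a template whose opening is narrower
  than its cavity cannot be seated — is not performed.
- Tangential (non-transversal) contacts are rejected by the merge rather
  than resolved.
- The closed-loop stitch is aligned at a single correspondence, not
  globally optimised over rotations; for convex, comparably sampled
  borders the difference is negligible.
- Coplanar boolean overlaps are handled by edge–edge intersection points
  only, which suffices for transversal unions but not for large coplanar
  contact regions.
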