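# guideforge

Semi-automatic design of patient-specific surgical templates (drill and
cutting guides) from CT-derived anatomy meshes.

A surgical template is a 3D-printed part whose inner face is the exact
negative of the patient's bone or dentition, so it seats uniquely on the
surgical site; drilling tubes embedded in it steer the drill along the
preoperatively planned implant axes. `guideforge` turns an anatomy surface
mesh (STL), a user-indicated closed border loop, a template thickness and a
set of planned drill axes into a watertight template mesh ready for 3D
printing.

## Method

The pipeline mirrors how such a guide is designed by hand, stage by stage:

1. **Inner surface segmentation.** The sparse user loop is interpolated with
   a closed Catmull–Rom spline, resampled at ~1 mm arc length and snapped
   onto the mesh. A cycle strictly along mesh edges is tracked under the
   loop, and every mesh vertex `P` receives a signed scalar: the minimum
   distance `min_s dist(P, segment_s)` to the loop polyline, positive on the
   side of a user hint point. Triangles whose vertices change sign are split
   at linearly interpolated zero crossings (`t = |s_a| / (|s_a| + |s_b|)`),
   so the cut border is smooth rather than jagged along triangle edges. The
   cost is O(N·n) for N mesh vertices and an n-point loop.
2. **Offset surface.** The unsigned distance field of the inner surface is
   sampled on a padded voxel grid (exact point-to-triangle distances) and
   contoured with marching cubes at iso-value = template thickness,
   producing a closed iso-distance surface `{x : dist(x, inner) = t}` —
   robust where direct normal offsetting would tear or self-intersect.
3. **Outer surface.** The inner border is subsampled, projected onto the
   offset along window-averaged vertex normals, and the offset is clipped
   with the same signed-scalar segmentation; the part on the inner surface's
   outward side is the template's top face.
4. **Ruled side wall.** The inner and outer border loops `P_0..P_{m-1}`,
   `Q_0..Q_{n-1}` are zipped with a triangle strip (one contour segment plus
   two spans `P_iQ_j` per triangle, m + n − 2 triangles in open mode). The
   strip minimising total span length is the shortest monotone path through
   the directed span grid, found with a label-setting dynamic program
   (`Dis_{i,j} = min(Dis_{i-1,j}, Dis_{i,j-1}) + |P_iQ_j|`).
5. **Drilling tubes.** Each planned axis becomes an annular cylinder.
   Tube and shell are merged by a union limited to what a guide needs:
   OBB-tree collision detection, edge-based triangle–triangle intersection,
   removal of marked triangles, ray-parity selection of the outside
   fragments and ruled seams along the intersection polylines.

## Worked example

```sh
guideforge fixtures --kind ridge --out ridge.stl --plan-out plan.json --seed 7
guideforge template --mesh ridge.stl --plan plan.json --out template.stl --report report.json
```

prints

```
wrote ridge.stl: 1681 vertices, 3200 faces
wrote plan.json
wrote template.stl: 8222 faces, closed, volume 1327.7 mm^3
wrote report.json
```

The ridge fixture is a 40 mm sinusoidal relief standing in for a jaw or
vertebra patch; the seeded plan lays an eight-point border loop over its
middle and one drilling tube through the loop region. The resulting
template is closed (every edge shared by exactly two faces — a 3D-printable
solid), and its volume exceeds the tube-less shell's because the tube
collar is unioned in. `report.json` lists per-stage element counts and
durations (inner surface segmentation, offset, border projection, outer
surface, ruled connection, boolean merge).

The same stages are available individually (`guideforge segment`, `offset`,
`outer`, `stitch`, `merge`) and as library functions
(`guideforge.design_template`, `segment_inner_surface`, ...).

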