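"""Offset (iso-distance) surface of the inner surface via a distance field.

Direct triangle/vertex normal offsetting leaves gaps or self-intersections in
concave regions, and the template's outer surface only needs the general
trend of the anatomy, not its detail.  So the offset surface is built the
robust way: sample the unsigned distance to the inner surface on a regular
voxel grid covering its padded bounding box, then contour the grid at
iso-value = template thickness with marching cubes.  The iso-set of a
distance-to-compact-set function is a closed surface whenever it stays inside
the grid, so the result is watertight by construction.

Grid node distances are *exact* point-to-triangle minima (KD-pruned, equal to
a brute-force scan), not vertex-sampling approximations; the per-vertex
offset error is then bounded by the marching-cubes linear-interpolation
error, i.e. by one voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import marching_cubes

from .mesh_core import MeshError, MeshProximity, TriangleMesh, weld_vertices

#: refuse to allocate grids larger than this many nodes.
DEFAULT_NODE_BUDGET = 20_000_000


class OffsetError(ValueError):
    """Raised for unusable grid parameters or a clipped isosurface."""


@dataclass
class DistanceGrid:
    """Regular voxel grid of unsigned distances (mm) to the inner surface."""

    origin: np.ndarray
    voxel: float
    values: np.ndarray  # (nx, ny, nz)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def default_voxel(thickness: float) -> float:
    """Default grid resolution: a quarter of the template thickness."""
    return thickness / 4.0


def default_padding(thickness: float) -> float:
    """Default bounding-box expansion: twice the template thickness."""
    return 2.0 * thickness


def build_distance_field(
    inner: TriangleMesh,
    voxel: float,
    padding: float,
    node_budget: int = DEFAULT_NODE_BUDGET,
) -> DistanceGrid:
    """Sample exact min distance to ``inner`` on a padded regular grid."""
    if inner.n_faces == 0:
        raise OffsetError("inner surface is empty")
    if voxel <= 0:
        raise OffsetError("voxel size must be positive")
    lo, hi = inner.bounds()
    lo = lo - padding
    hi = hi + padding
    dims = np.ceil((hi - lo) / voxel).astype(int) + 1
    n_nodes = int(np.prod(dims))
    if n_nodes > node_budget:
        raise OffsetError(
            f"grid of {dims.tolist()} = {n_nodes} nodes exceeds the budget "
            f"({node_budget}); use a larger voxel size"
        )
    axes = [lo[k] + voxel * np.arange(dims[k]) for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    nodes = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    prox = MeshProximity(inner)
    values = np.empty(n_nodes)
    chunk = 65536
    for s in range(0, n_nodes, chunk):
        values[s : s + chunk] = prox.query(nodes[s : s + chunk])[0]
    return DistanceGrid(origin=lo, voxel=float(voxel), values=values.reshape(dims))


def extract_offset_surface(grid: DistanceGrid, thickness: float) -> TriangleMesh:
    """Marching-cubes isosurface of the distance grid at ``thickness``.

    Raises :class:`OffsetError` if the isosurface would touch the grid
    boundary (increase the padding).
    """
    if thickness <= 0:
        raise OffsetError("thickness must be positive")
    v = grid.values
    boundary_min = min(
        v[0].min(), v[-1].min(), v[:, 0].min(), v[:, -1].min(),
        v[:, :, 0].min(), v[:, :, -1].min(),
    )
    if boundary_min <= thickness:
        raise OffsetError(
            f"isosurface at {thickness} mm reaches the grid boundary "
            f"(boundary min distance {boundary_min:.3f} mm); increase the padding"
        )
    if v.min() > thickness:
        raise OffsetError(f"no isosurface: grid minimum {v.min():.3f} mm > {thickness} mm")
    verts, faces, _, _ = marching_cubes(
        v, level=thickness, spacing=(grid.voxel,) * 3
    )
    verts = verts + grid.origin
    w_verts, w_faces = weld_vertices(verts, faces, tol=1e-9)
    mesh = TriangleMesh(w_verts, w_faces)
    closed, loops = _safe_check_closed(mesh)
    if not closed:
        raise OffsetError(
            f"offset surface is not closed ({len(loops)} boundary loops); "
            "increase padding or refine the voxel size"
        )
    return mesh


def _safe_check_closed(mesh: TriangleMesh):
    from .mesh_core import check_closed

    try:
        return check_closed(mesh)
    except MeshError as exc:
        raise OffsetError(f"marching cubes produced a non-manifold surface: {exc}") from exc
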