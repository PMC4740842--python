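"""Clipping the closed offset surface into the template's outer surface.

The outer surface's outline should follow the inner surface's border, so the
inner border points are carried over: the inner boundary loop is ordered,
subsampled with a stride (the *sampling step*), and each sample is projected
onto the offset surface along a smoothed normal — the average of the
sample's vertex normal and the normals of its nearest boundary neighbors,
which keeps the projected loop from self-intersecting where the border
wiggles.  The projected loop then drives the same signed-distance clip used
for the inner surface, and of the two parts of the offset the one on the
inner surface's outward-normal side (the component a normal ray from the
patch interior hits first) is the outer surface.
"""

from __future__ import annotations

import logging

import numpy as np

from .loop_input import SurfaceLoop, _self_intersects
from .mesh_core import MeshProximity, TriangleMesh, ray_mesh_hits, vertex_normals
from .ruled_stitcher import ordered_boundary_loop
from .segmentation import (
    SegmentationError,
    clip_by_scalar,
    point_to_polyline,
    signed_vertex_distances,
    track_edge_loop,
)

log = logging.getLogger("guideforge")

DEFAULT_SAMPLING_STEP = 10
DEFAULT_NORMAL_WINDOW = 5


class OuterSurfaceError(ValueError):
    """Raised when border projection or side selection fails."""


def project_border_loop(
    inner: TriangleMesh,
    offset: TriangleMesh,
    sampling_step: int = DEFAULT_SAMPLING_STEP,
    normal_window: int = DEFAULT_NORMAL_WINDOW,
) -> SurfaceLoop:
    """Project subsampled inner-border points onto the offset surface.

    Every ``sampling_step``-th ordered boundary point is cast along its
    window-averaged outward normal; a ray that misses falls back to the
    closest point on the offset (logged).  A self-intersecting projected
    loop raises :class:`OuterSurfaceError` suggesting a larger step.
    """
    if sampling_step < 1:
        raise ValueError("sampling_step must be >= 1")
    loop = ordered_boundary_loop(inner)
    samples = loop[::sampling_step]
    if len(samples) < 3:
        raise OuterSurfaceError(
            f"sampling step {sampling_step} leaves {len(samples)} border points; "
            "use a smaller step"
        )
    normals = vertex_normals(inner)
    m = len(loop)
    pos_in_loop = {int(v): k for k, v in enumerate(loop)}
    half = max(1, normal_window // 2)

    prox = MeshProximity(offset)
    pts, host = [], []
    misses = 0
    for v in samples:
        k = pos_in_loop[int(v)]
        window = [loop[(k + o) % m] for o in range(-half, half + 1)]
        n_avg = normals[window].mean(axis=0)
        norm = np.linalg.norm(n_avg)
        if norm == 0:
            n_avg = normals[int(v)]
            norm = np.linalg.norm(n_avg)
        n_avg = n_avg / norm
        origin = inner.vertices[int(v)]
        ts, faces = ray_mesh_hits(origin, n_avg, offset)
        if len(ts):
            pts.append(origin + ts[0] * n_avg)
            host.append(int(faces[0]))
        else:
            misses += 1
            d, c, f = prox.query(origin[None])
            pts.append(c[0])
            host.append(int(f[0]))
    if misses:
        log.info("project_border_loop: %d/%d rays missed; fell back to closest point",
                 misses, len(samples))
    pts = np.asarray(pts)
    bad = _self_intersects(pts)
    if bad is not None:
        raise OuterSurfaceError(
            f"projected border loop self-intersects (segments {bad[0]}/{bad[1]}); "
            "increase the sampling step"
        )
    return SurfaceLoop(pts, np.asarray(host))


def _interior_ray(inner: TriangleMesh) -> tuple[np.ndarray, np.ndarray]:
    """An interior inner-surface point and its outward normal.

    The vertex farthest from the border is used so the ray leaves from well
    inside the patch.
    """
    loop = ordered_boundary_loop(inner)
    d, _ = point_to_polyline(inner.vertices, inner.vertices[loop])
    v = int(np.argmax(d))
    return inner.vertices[v], vertex_normals(inner)[v]


def extract_outer_surface(
    offset: TriangleMesh,
    loop: SurfaceLoop,
    inner: TriangleMesh,
) -> TriangleMesh:
    """Clip the closed offset along the projected loop; keep the outer part.

    The kept side is found by casting a ray from an interior point of the
    inner surface along its outward normal: the first hit on the offset
    marks the outer component, which becomes the positive side of the
    signed-distance clip.
    """
    origin, normal = _interior_ray(inner)
    ts, _ = ray_mesh_hits(origin, normal, offset)
    if len(ts) == 0:
        raise OuterSurfaceError(
            "side-selection ray from the inner surface missed the offset; "
            "pass an explicit hint or check the surface orientation"
        )
    hint = origin + ts[0] * normal
    edge_loop = track_edge_loop(loop, offset)
    try:
        field = signed_vertex_distances(offset, loop, edge_loop, hint)
    except SegmentationError as exc:
        raise OuterSurfaceError(f"projected loop cannot clip the offset: {exc}") from exc
    outer = clip_by_scalar(offset, field, keep="positive")
    if outer.n_faces == 0:
        raise OuterSurfaceError("outer-surface clip kept no triangles")
    return outer
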