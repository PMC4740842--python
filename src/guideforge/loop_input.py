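"""User control loops and their densification onto the mesh surface.

A surgeon indicates the template border as a sparse closed loop of control
points near the anatomy surface.  For a smooth segmentation border the loop
is interpolated with a closed cardinal spline (Catmull-Rom tension 0.5),
resampled at roughly uniform arc length, and every sample snapped to its
closest point on the mesh (in an interactive setting the samples would be
projected through the camera; in a batch library the geometric closest-point
projection plays that role).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh_core import MeshProximity, TriangleMesh

#: cardinal-spline tension; 0.5 is the Catmull-Rom spline.
SPLINE_TENSION = 0.5

#: default resampling interval along the loop, mm.
DEFAULT_STEP_MM = 1.0

#: snapping farther than this is considered a user error (wrong frame), mm.
DEFAULT_MAX_SNAP_MM = 10.0


class LoopError(ValueError):
    """Raised for degenerate or self-intersecting loops."""


@dataclass
class ControlLoop:
    """Closed ordered loop of user control points (mm)."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        if len(self.points) < 3:
            raise LoopError("a control loop needs at least 3 points")
        nxt = np.roll(self.points, -1, axis=0)
        if np.any(np.linalg.norm(nxt - self.points, axis=1) == 0):
            raise LoopError("consecutive control points coincide")
        bad = _self_intersects(self.points)
        if bad is not None:
            raise LoopError(f"control loop self-intersects (segments {bad[0]} and {bad[1]})")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class SurfaceLoop:
    """Closed ordered loop of on-surface points with their host faces."""

    points: np.ndarray
    host_faces: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        self.host_faces = np.asarray(self.host_faces, dtype=np.int64)
        if len(self.points) < 1:
            raise LoopError("a surface loop needs at least 1 point")

    def __len__(self) -> int:
        return len(self.points)


def _segment_pair_distance(p1, q1, p2, q2) -> float:
    """Minimum distance between 3D segments p1q1 and p2q2."""
    d1, d2 = q1 - p1, q2 - p2
    r = p1 - p2
    a = d1 @ d1
    e = d2 @ d2
    f = d2 @ r
    c = d1 @ r
    b = d1 @ d2
    denom = a * e - b * b
    s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > 1e-300 else 0.0
    t = (b * s + f) / e if e > 1e-300 else 0.0
    if t < 0.0:
        t = 0.0
        s = np.clip(-c / a, 0.0, 1.0) if a > 1e-300 else 0.0
    elif t > 1.0:
        t = 1.0
        s = np.clip((b - c) / a, 0.0, 1.0) if a > 1e-300 else 0.0
    return float(np.linalg.norm((p1 + s * d1) - (p2 + t * d2)))


def _self_intersects(points: np.ndarray, tol: float = 1e-9):
    """Return indices of two non-adjacent crossing segments, or None."""
    n = len(points)
    nxt = np.roll(points, -1, axis=0)
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:  # adjacent through the wrap
                continue
            if _segment_pair_distance(points[i], nxt[i], points[j], nxt[j]) < tol:
                return i, j
    return None


def snap_to_surface(
    points: np.ndarray,
    mesh: TriangleMesh,
    max_snap: float = DEFAULT_MAX_SNAP_MM,
    proximity: MeshProximity | None = None,
) -> SurfaceLoop:
    """Replace each point with its closest point on the mesh surface.

    Raises :class:`LoopError` if any point is farther than ``max_snap`` mm
    from the surface (almost always a units or coordinate-frame mistake).
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    prox = proximity or MeshProximity(mesh)
    dist, closest, faces = prox.query(points)
    if np.any(dist > max_snap):
        i = int(np.argmax(dist))
        raise LoopError(
            f"point {i} at {points[i].tolist()} is {dist[i]:.2f} mm from the surface "
            f"(max allowed {max_snap} mm)"
        )
    return SurfaceLoop(closest, faces)


def _cardinal_spline_closed(
    control: np.ndarray, samples_per_seg: int, tension: float = SPLINE_TENSION
) -> np.ndarray:
    """Dense samples of the closed cardinal spline through ``control``.

    Hermite form with tangents ``T_i = tension * (P_{i+1} - P_{i-1})``; the
    first sample of each segment is the control point itself.
    """
    n = len(control)
    prev = np.roll(control, 1, axis=0)
    nxt = np.roll(control, -1, axis=0)
    tangents = tension * (nxt - prev)
    u = np.linspace(0.0, 1.0, samples_per_seg, endpoint=False)
    h00 = 2 * u**3 - 3 * u**2 + 1
    h10 = u**3 - 2 * u**2 + u
    h01 = -2 * u**3 + 3 * u**2
    h11 = u**3 - u**2
    segs = []
    for i in range(n):
        j = (i + 1) % n
        seg = (
            h00[:, None] * control[i]
            + h10[:, None] * tangents[i]
            + h01[:, None] * control[j]
            + h11[:, None] * tangents[j]
        )
        segs.append(seg)
    return np.concatenate(segs), samples_per_seg


def densify_loop(
    loop: ControlLoop,
    mesh: TriangleMesh,
    step: float = DEFAULT_STEP_MM,
    max_snap: float = DEFAULT_MAX_SNAP_MM,
    proximity: MeshProximity | None = None,
) -> SurfaceLoop:
    """Spline-interpolate, resample at ~``step`` mm and snap onto the surface.

    Each spline segment keeps its starting control point and is subdivided at
    arc-length intervals of about ``step``, so every control point appears in
    the output.  If ``step`` exceeds the loop length the control points
    themselves are snapped and returned.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    control = loop.points
    dense, per_seg = _cardinal_spline_closed(control, samples_per_seg=64)
    seg_len = np.linalg.norm(np.diff(np.vstack([dense, dense[:1]]), axis=0), axis=1)
    total = float(seg_len.sum())
    if step >= total:
        out = snap_to_surface(control, mesh, max_snap, proximity)
        _check_surface_loop(out)
        return out
    samples = []
    for i in range(len(control)):
        chunk = dense[i * per_seg : (i + 1) * per_seg]
        chunk = np.vstack([chunk, dense[((i + 1) * per_seg) % len(dense)]])
        d = np.linalg.norm(np.diff(chunk, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(d)])
        n_sub = max(1, int(np.ceil(arc[-1] / step)))
        targets = np.linspace(0.0, arc[-1], n_sub, endpoint=False)
        samples.append(
            np.stack([np.interp(targets, arc, chunk[:, k]) for k in range(3)], axis=1)
        )
    pts = np.concatenate(samples)
    out = snap_to_surface(pts, mesh, max_snap, proximity)
    _check_surface_loop(out)
    return out


def _check_surface_loop(loop: SurfaceLoop) -> None:
    pts = loop.points
    nxt = np.roll(pts, -1, axis=0)
    if np.any(np.linalg.norm(nxt - pts, axis=1) < 1e-12):
        raise LoopError(
            "snapping produced duplicate consecutive points; use a larger step "
            "or add control points"
        )
    bad = _self_intersects(pts)
    if bad is not None:
        raise LoopError(
            f"snapped loop self-intersects (segments {bad[0]} and {bad[1]}); "
            "use a smaller step or more control points"
        )
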