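"""Deterministic synthetic anatomy-like meshes and demo plans.

Real guide design starts from CT-derived STL surfaces that cannot ship with
a library, so every stage is exercised on procedurally generated stand-ins:
an icosphere (closed, analytically checkable), and a sinusoidal-ridge
height field whose gentle relief plays the role of a jaw or vertebra patch.
``make_demo_plan`` lays a reproducible rectangle-ish control loop and tube
axes over a mesh from a single integer seed; the design algorithms
themselves are RNG-free.
"""

from __future__ import annotations

import json

import numpy as np
import trimesh as _trimesh

from .mesh_core import TriangleMesh, vertex_normals
from .loop_input import snap_to_surface


def make_sphere(radius: float = 1.0, subdivisions: int = 2) -> TriangleMesh:
    """Icosphere: 20 * 4**subdivisions faces, all vertices exactly at ``radius``."""
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    ico = _trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    v = np.asarray(ico.vertices, dtype=np.float64)
    v = radius * v / np.linalg.norm(v, axis=1, keepdims=True)
    return TriangleMesh(v, np.asarray(ico.faces, dtype=np.int64))


def make_ridge(size: float = 40.0, amplitude: float = 4.0, resolution: int = 25) -> TriangleMesh:
    """Open sinusoidal height field over a ``size`` x ``size`` square (mm).

    ``z = amplitude * sin(pi x / size) * sin(pi y / size)`` on a regular
    ``resolution x resolution`` grid: 2*(resolution-1)**2 faces, single
    boundary loop of 4*(resolution-1) edges.
    """
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    r = resolution
    xs = np.linspace(0.0, size, r)
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    gz = amplitude * np.sin(np.pi * gx / size) * np.sin(np.pi * gy / size)
    vertices = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    faces = []
    for i in range(r - 1):
        for j in range(r - 1):
            a = i * r + j
            b = a + 1
            c = a + r
            d = c + 1
            # CCW seen from +z (outward normal up)
            faces.append((a, c, b))
            faces.append((b, c, d))
    return TriangleMesh(vertices, np.asarray(faces, dtype=np.int64))


def make_hemisphere(radius: float = 1.0, subdivisions: int = 2, z_min: float = 0.05) -> TriangleMesh:
    """Open spherical cap: icosphere faces whose vertices all have z > ``z_min``."""
    sphere = make_sphere(radius, subdivisions)
    keep = (sphere.vertices[sphere.faces, 2] > z_min * radius).all(axis=1)
    faces = sphere.faces[keep]
    used = np.unique(faces)
    remap = np.full(sphere.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriangleMesh(sphere.vertices[used], remap[faces])


def make_demo_plan(
    mesh: TriangleMesh,
    seed: int,
    n_tubes: int = 1,
    thickness: float = 2.5,
    densify_step: float | None = None,
) -> dict:
    """Seeded, reproducible plan: a rectangle-ish control loop plus tube axes.

    The loop is laid out in the middle of the mesh's xy footprint with a
    small seeded jitter and snapped onto the surface; tubes pass through the
    loop region along the local surface normal, long enough to straddle a
    template of the given thickness.
    """
    rng = np.random.default_rng(seed)
    lo, hi = mesh.bounds()
    center = (lo + hi) / 2.0
    span = hi - lo
    half = 0.28 * span[:2]
    corners = np.array(
        [[-1, -1], [0, -1], [1, -1], [1, 0], [1, 1], [0, 1], [-1, 1], [-1, 0]],
        dtype=np.float64,
    )
    jitter = rng.uniform(-0.05, 0.05, size=(len(corners), 2)) * span[:2]
    pts_xy = center[:2] + corners * half + jitter
    raised = np.column_stack([pts_xy, np.full(len(pts_xy), hi[2] + 0.1 * span[2] + 1.0)])
    snapped = snap_to_surface(raised, mesh, max_snap=1e9)
    control = snapped.points

    normals = vertex_normals(mesh)
    tubes = []
    for _ in range(n_tubes):
        target_xy = center[:2] + rng.uniform(-0.1, 0.1, size=2) * span[:2]
        d2 = np.linalg.norm(mesh.vertices[:, :2] - target_xy, axis=1)
        v = int(np.argmin(d2))
        n = normals[v]
        n = n / np.linalg.norm(n)
        length = float(4.0 * thickness + 2.0)
        origin = mesh.vertices[v] - 0.25 * length * n
        tubes.append(
            {
                "origin": [round(float(x), 6) for x in origin],
                "direction": [round(float(x), 6) for x in n],
                "inner_radius_mm": 1.25,
                "outer_radius_mm": 2.5,
                "length_mm": length,
            }
        )

    loop_span = float(np.linalg.norm(2 * half))
    plan = {
        "control_points": [[round(float(x), 6) for x in p] for p in control],
        "densify_step_mm": round(
            float(densify_step if densify_step is not None else max(loop_span / 40.0, 0.25)), 6
        ),
        "thickness_mm": float(thickness),
        "tubes": tubes,
    }
    return plan


def plan_to_json(plan: dict) -> str:
    """Canonical JSON serialisation (sorted keys): same plan -> same bytes."""
    return json.dumps(plan, sort_keys=True, indent=2)
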