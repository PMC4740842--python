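"""Drilling-tube meshes from planned implant axes.

A drilling tube is an annular cylinder whose bore guides the surgical drill
along the preoperatively planned implant axis: outer wall, inner wall with
reversed winding, and two flat annulus caps.  Callers position the tube so
it straddles the template shell before the boolean union.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .mesh_core import TriangleMesh

DEFAULT_SEGMENTS = 32


class TubeSpec(BaseModel):
    """Axis, radii and length of one drilling tube (mm)."""

    origin: tuple[float, float, float]
    direction: tuple[float, float, float]
    inner_radius_mm: float = Field(gt=0)
    outer_radius_mm: float = Field(gt=0)
    length_mm: float = Field(gt=0)
    segments: int = Field(default=DEFAULT_SEGMENTS, ge=3)
    rings: int | None = Field(default=None, ge=1)  # axial wall subdivisions; None = auto

    @field_validator("direction")
    @classmethod
    def _nonzero_direction(cls, v):
        if np.linalg.norm(v) == 0:
            raise ValueError("direction must be non-zero")
        return v

    @model_validator(mode="after")
    def _radii_ordered(self):
        if not self.inner_radius_mm < self.outer_radius_mm:
            raise ValueError(
                f"inner radius ({self.inner_radius_mm}) must be smaller than "
                f"outer radius ({self.outer_radius_mm})"
            )
        return self

    @property
    def unit_direction(self) -> np.ndarray:
        d = np.asarray(self.direction, dtype=np.float64)
        return d / np.linalg.norm(d)


def _axis_frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to ``direction`` (deterministic choice)."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(direction @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(direction, ref)
    u /= np.linalg.norm(u)
    return u, np.cross(direction, u)


def make_tube(spec: TubeSpec) -> TriangleMesh:
    """Watertight annular cylinder spanning origin..origin + length*direction.

    Outward-oriented: outer wall normals point away from the axis, bore wall
    normals into the bore, caps along -/+ axis.  Walls are subdivided into
    roughly isotropic axial rings (overridable via ``spec.rings``) so that
    a boolean cut through the tube removes only a narrow band of triangles.
    """
    k = spec.segments
    d = spec.unit_direction
    o = np.asarray(spec.origin, dtype=np.float64)
    u, v = _axis_frame(d)
    theta = 2.0 * np.pi * np.arange(k) / k
    ring = np.cos(theta)[:, None] * u + np.sin(theta)[:, None] * v
    circ_step = 2.0 * np.pi * spec.outer_radius_mm / k
    rings = spec.rings or max(1, int(np.ceil(spec.length_mm / circ_step)))
    levels = o + np.linspace(0.0, spec.length_mm, rings + 1)[:, None] * d

    # vertex layout: outer wall rings (rings+1 levels), then inner wall rings
    outer_pts = (levels[:, None, :] + spec.outer_radius_mm * ring[None, :, :]).reshape(-1, 3)
    inner_pts = (levels[:, None, :] + spec.inner_radius_mm * ring[None, :, :]).reshape(-1, 3)
    vertices = np.concatenate([outer_pts, inner_pts])
    n_out = len(outer_pts)

    def O(level: int, i: int) -> int:
        return level * k + (i % k)

    def I(level: int, i: int) -> int:
        return n_out + level * k + (i % k)

    faces = []
    for lv in range(rings):
        for i in range(k):
            j = i + 1
            # outer wall, outward
            faces.append((O(lv, i), O(lv, j), O(lv + 1, j)))
            faces.append((O(lv, i), O(lv + 1, j), O(lv + 1, i)))
            # inner wall, reversed winding (normals into the bore)
            faces.append((I(lv, i), I(lv + 1, j), I(lv, j)))
            faces.append((I(lv, i), I(lv + 1, i), I(lv + 1, j)))
    for i in range(k):
        j = i + 1
        # bottom cap (normal along -direction)
        faces.append((O(0, i), I(0, j), O(0, j)))
        faces.append((O(0, i), I(0, i), I(0, j)))
        # top cap (normal along +direction)
        faces.append((O(rings, i), O(rings, j), I(rings, j)))
        faces.append((O(rings, i), I(rings, j), I(rings, i)))
    return TriangleMesh(vertices, np.asarray(faces, dtype=np.int64))
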