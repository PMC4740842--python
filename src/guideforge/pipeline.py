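"""End-to-end template design: anatomy mesh + plan -> watertight template.

Stages, in order:

1. *Inner surface segmentation* — densify the user loop, track it onto mesh
   edges, sign the vertex distances and clip: the tissue-contacting patch.
2. *Offset of inner surface* — distance field on a padded voxel grid,
   contoured at the template thickness.
3. *Generation of points for outer surface segmentation* — inner border
   subsampled and projected onto the offset along averaged normals.
4. *Outer surface segmentation* — clip the offset with the projected loop,
   keep the part on the inner surface's outward side.
5. *Connection of inner and outer surfaces* — closed ruled-surface side
   wall between the two border loops; welded into the initial template.
6. *Boolean operation* — each drilling tube is built and union-merged in.

The run report lists per-stage element counts and durations (counts are
contractual, durations informational).
"""

from __future__ import annotations

import logging
import time

import numpy as np
from pydantic import BaseModel, Field

from . import offsetter
from .boolean_merge import merge_union
from .loop_input import ControlLoop, DEFAULT_STEP_MM
from .mesh_core import TriangleMesh, check_closed, concatenate, orient_consistently
from .outer_surface import (
    DEFAULT_NORMAL_WINDOW,
    DEFAULT_SAMPLING_STEP,
    extract_outer_surface,
    project_border_loop,
)
from .ruled_stitcher import LoopPair, ordered_boundary_loop, stitch_loops
from .segmentation import segment_inner_surface
from .tube_builder import TubeSpec, make_tube

log = logging.getLogger("guideforge")


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


class PipelineConfig(BaseModel):
    """Tunable defaults shared by all stages (distances in mm)."""

    densify_step_mm: float = Field(default=DEFAULT_STEP_MM, gt=0)
    voxel_mm: float | None = Field(default=None, gt=0)  # default: thickness / 4
    padding_mm: float | None = Field(default=None, gt=0)  # default: 2 * thickness
    sampling_step: int = Field(default=DEFAULT_SAMPLING_STEP, ge=1)
    normal_window: int = Field(default=DEFAULT_NORMAL_WINDOW, ge=1)
    tube_segments: int = Field(default=32, ge=3)


class Plan(BaseModel):
    """The preoperative plan: cutting loop, thickness and drill axes."""

    control_points: list[tuple[float, float, float]] = Field(min_length=3)
    thickness_mm: float = Field(default=2.5, gt=0)
    densify_step_mm: float | None = Field(default=None, gt=0)
    keep_hint: tuple[float, float, float] | None = None
    tubes: list[TubeSpec] = Field(default_factory=list)


def _stage(report: dict, name: str):
    class _Timer:
        def __enter__(self):
            report["stages"].setdefault(name, {})
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            report["stages"].setdefault(name, {})["time_s"] = round(
                time.perf_counter() - self.t0, 4
            )
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            return False

    return _Timer()


def design_template(mesh: TriangleMesh, plan: Plan | dict, config: PipelineConfig | None = None):
    """Run the full design pipeline; returns ``(template, report)``.

    The returned template is a closed, consistently outward-oriented mesh;
    closure failure raises :class:`PipelineError` with the boundary edges in
    the message.
    """
    if isinstance(plan, dict):
        plan = Plan.model_validate(plan)
    config = config or PipelineConfig()
    thickness = plan.thickness_mm
    step = plan.densify_step_mm or config.densify_step_mm
    voxel = config.voxel_mm or offsetter.default_voxel(thickness)
    padding = config.padding_mm or offsetter.default_padding(thickness)

    report: dict = {
        "input": {"points": mesh.n_vertices, "triangles": mesh.n_faces},
        "parameters": {
            "thickness_mm": thickness,
            "densify_step_mm": step,
            "voxel_mm": voxel,
            "padding_mm": padding,
            "sampling_step": config.sampling_step,
            "drilling_tubes": len(plan.tubes),
        },
        "stages": {},
    }

    control = ControlLoop(np.asarray(plan.control_points))
    hint = (
        np.asarray(plan.keep_hint, dtype=np.float64)
        if plan.keep_hint is not None
        else _default_hint(mesh, control)
    )

    with _stage(report, "Inner surface segmentation"):
        inner, dense_loop, _field = segment_inner_surface(mesh, control, hint, step=step)
        closed, loops = check_closed(inner)
        if closed or len(loops) != 1:
            raise PipelineError(
                f"inner surface should be open with one boundary loop, got "
                f"closed={closed}, loops={len(loops)}"
            )
        report["stages"]["Inner surface segmentation"].update(
            {
                "edge_points": len(dense_loop),
                "points": inner.n_vertices,
                "triangles": inner.n_faces,
            }
        )
        log.info("inner surface: %d triangles, %d points", inner.n_faces, inner.n_vertices)

    with _stage(report, "Offset of inner surface"):
        grid = offsetter.build_distance_field(inner, voxel=voxel, padding=padding)
        offset = offsetter.extract_offset_surface(grid, thickness)
        report["stages"]["Offset of inner surface"].update(
            {"grid_nodes": int(np.prod(grid.shape)), "triangles": offset.n_faces}
        )

    with _stage(report, "Generation of points for outer surface segmentation"):
        border = project_border_loop(
            inner, offset, config.sampling_step, config.normal_window
        )
        report["stages"]["Generation of points for outer surface segmentation"].update(
            {"points": len(border)}
        )

    with _stage(report, "Outer surface segmentation"):
        outer = extract_outer_surface(offset, border, inner)
        closed, loops = check_closed(outer)
        if closed or len(loops) != 1:
            raise PipelineError(
                f"outer surface should be open with one boundary loop, got "
                f"closed={closed}, loops={len(loops)}"
            )
        report["stages"]["Outer surface segmentation"].update(
            {"points": outer.n_vertices, "triangles": outer.n_faces}
        )

    with _stage(report, "Connection of inner and outer surfaces"):
        p_loop = inner.vertices[ordered_boundary_loop(inner)]
        q_loop = outer.vertices[ordered_boundary_loop(outer)]
        wall = stitch_loops(LoopPair(p_loop, q_loop), closed=True, auto_reverse=True)
        shell = concatenate([inner, outer, wall], weld_tol=1e-9)
        closed, loops = check_closed(shell)
        if not closed:
            raise PipelineError(
                f"initial template is not closed: {len(loops)} boundary loops; "
                f"first loop vertices: {loops[0][:12]}"
            )
        shell = orient_consistently(shell, outward=True)
        report["stages"]["Connection of inner and outer surfaces"].update(
            {"wall_triangles": wall.n_faces, "shell_triangles": shell.n_faces}
        )

    template = shell
    if plan.tubes:
        with _stage(report, "Boolean operation"):
            for k, spec in enumerate(plan.tubes):
                if spec.segments != config.tube_segments:
                    spec = spec.model_copy(update={"segments": config.tube_segments})
                tube = make_tube(spec)
                template = merge_union(template, tube)
            template = orient_consistently(template, outward=True)
            report["stages"]["Boolean operation"].update(
                {"tubes": len(plan.tubes), "triangles": template.n_faces}
            )

    closed, loops = check_closed(template)
    if not closed:
        edges = [(loop[i], loop[(i + 1) % len(loop)]) for loop in loops for i in range(len(loop))]
        raise PipelineError(f"final template is not closed; boundary edges: {edges[:20]}")
    report["output"] = {
        "points": template.n_vertices,
        "triangles": template.n_faces,
        "closed": True,
        "volume_mm3": round(template.signed_volume(), 6),
    }
    return template, report


def _default_hint(mesh: TriangleMesh, control: ControlLoop) -> np.ndarray:
    """Inside-the-loop hint: the mesh vertex nearest the loop centroid."""
    centroid = control.points.mean(axis=0)
    v = int(np.argmin(np.linalg.norm(mesh.vertices - centroid, axis=1)))
    return mesh.vertices[v]
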