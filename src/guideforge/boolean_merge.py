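"""Collision detection and union-style merging of triangulated surfaces.

Adding a drilling tube to the template shell needs only one boolean flavour:
union.  The operation is decomposed into

1. *Collision detection*: OBB (oriented-bounding-box) trees over both meshes
   prune the triangle pairs; every surviving pair runs an edge-based test —
   each edge of one triangle against the other triangle's bounding box, then
   its plane, keeping the intersection point when it falls inside the
   triangle — symmetrically in both directions so both endpoints of the
   transversal intersection segment are recovered.  Both triangles of any
   intersecting pair are marked.
2. *Polyline extraction*: the per-pair segments are chained end to end into
   intersection polylines, closed for transversal closed-vs-closed contacts.
3. *Merging*: marked triangles are removed, splitting each surface into
   fragments; a fragment is kept iff it lies outside the other closed mesh
   (ray-parity test on a surface sample point).  Each kept fragment's ragged
   boundary is joined to its intersection polyline with a closed ruled-
   surface seam, and the pieces are welded into one watertight shell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .mesh_core import TriangleMesh, check_closed, concatenate, point_in_mesh
from .ruled_stitcher import LoopPair, ordered_boundary_loops, stitch_loops

log = logging.getLogger("guideforge")

DEFAULT_LEAF_SIZE = 4
COPLANAR_EPS = 1e-8  # on unit-normal alignment and plane offset
CHAIN_TOL = 1e-7  # endpoint matching when chaining segments into polylines


class MergeError(ValueError):
    """Raised when a union cannot be completed."""


# ---------------------------------------------------------------------------
# OBB tree
# ---------------------------------------------------------------------------


@dataclass
class ObbNode:
    center: np.ndarray
    axes: np.ndarray  # rows are the box axes
    half: np.ndarray
    tri_indices: np.ndarray | None = None
    children: tuple["ObbNode", "ObbNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None


@dataclass
class ObbTree:
    root: ObbNode
    mesh: TriangleMesh
    leaf_size: int = DEFAULT_LEAF_SIZE
    depth: int = field(default=0)


def _fit_obb(corners: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Covariance-aligned box over a point cloud: (center, axes, half-extents)."""
    mean = corners.mean(axis=0)
    cov = np.cov((corners - mean).T) if len(corners) > 1 else np.eye(3)
    cov = np.atleast_2d(cov)
    if cov.shape != (3, 3) or not np.all(np.isfinite(cov)):
        cov = np.eye(3)
    w, vecs = np.linalg.eigh(cov)
    axes = vecs.T[::-1]  # largest-variance axis first
    proj = (corners - mean) @ axes.T
    lo, hi = proj.min(axis=0), proj.max(axis=0)
    center = mean + ((lo + hi) / 2.0) @ axes
    half = (hi - lo) / 2.0
    return center, axes, half


def _build_node(mesh: TriangleMesh, tri_idx: np.ndarray, leaf_size: int, depth: int):
    corners = mesh.triangles[tri_idx].reshape(-1, 3)
    center, axes, half = _fit_obb(corners)
    node = ObbNode(center, axes, half)
    if len(tri_idx) <= leaf_size:
        node.tri_indices = tri_idx
        return node, depth
    centroids = mesh.triangles[tri_idx].mean(axis=1)
    axis = int(np.argmax(half))
    keys = (centroids - center) @ axes[axis]
    order = np.argsort(keys, kind="stable")
    mid = len(order) // 2
    left, right = tri_idx[order[:mid]], tri_idx[order[mid:]]
    if len(left) == 0 or len(right) == 0:  # degenerate split: halve by index
        mid = len(tri_idx) // 2
        left, right = tri_idx[:mid], tri_idx[mid:]
    ln, ld = _build_node(mesh, left, leaf_size, depth + 1)
    rn, rd = _build_node(mesh, right, leaf_size, depth + 1)
    node.children = (ln, rn)
    return node, max(ld, rd)


def build_obb_tree(mesh: TriangleMesh, leaf_size: int = DEFAULT_LEAF_SIZE) -> ObbTree:
    if mesh.n_faces == 0:
        raise MergeError("cannot build an OBB tree over an empty mesh")
    root, depth = _build_node(mesh, np.arange(mesh.n_faces), leaf_size, 0)
    return ObbTree(root, mesh, leaf_size, depth)


def obb_overlap(a: ObbNode, b: ObbNode, eps: float = 1e-12) -> bool:
    """Separating-axis test for two oriented boxes (15 candidate axes)."""
    r = a.axes @ b.axes.T  # rotation of b's axes into a's frame
    t = a.axes @ (b.center - a.center)
    abs_r = np.abs(r) + eps
    ea, eb = a.half, b.half
    for i in range(3):  # a's face axes
        if abs(t[i]) > ea[i] + eb @ abs_r[i]:
            return False
    for j in range(3):  # b's face axes
        if abs(t @ r[:, j]) > ea @ abs_r[:, j] + eb[j]:
            return False
    for i in range(3):  # edge-edge cross axes
        for j in range(3):
            i1, i2 = (i + 1) % 3, (i + 2) % 3
            j1, j2 = (j + 1) % 3, (j + 2) % 3
            ra = ea[i1] * abs_r[i2, j] + ea[i2] * abs_r[i1, j]
            rb = eb[j1] * abs_r[i, j2] + eb[j2] * abs_r[i, j1]
            if abs(t[i2] * r[i1, j] - t[i1] * r[i2, j]) > ra + rb:
                return False
    return True


def _leaf_pairs(a: ObbNode, b: ObbNode, out: list[tuple[np.ndarray, np.ndarray]]):
    if not obb_overlap(a, b):
        return
    if a.is_leaf and b.is_leaf:
        out.append((a.tri_indices, b.tri_indices))
    elif a.is_leaf:
        _leaf_pairs(a, b.children[0], out)
        _leaf_pairs(a, b.children[1], out)
    elif b.is_leaf or a.half.max() >= b.half.max():
        _leaf_pairs(a.children[0], b, out)
        _leaf_pairs(a.children[1], b, out)
    else:
        _leaf_pairs(a, b.children[0], out)
        _leaf_pairs(a, b.children[1], out)


# ---------------------------------------------------------------------------
# triangle-pair intersection
# ---------------------------------------------------------------------------


def _inside_triangle(p: np.ndarray, tri: np.ndarray, tol: float = 1e-10) -> bool:
    """Barycentric containment of an (on-plane) point."""
    a, b, c = tri
    v0, v1, v2 = c - a, b - a, p - a
    d00 = v0 @ v0
    d01 = v0 @ v1
    d11 = v1 @ v1
    d20 = v2 @ v0
    d21 = v2 @ v1
    denom = d00 * d11 - d01 * d01
    if denom == 0:
        return False
    u = (d11 * d20 - d01 * d21) / denom
    v = (d00 * d21 - d01 * d20) / denom
    return u >= -tol and v >= -tol and u + v <= 1 + tol


def _edges_vs_triangle(t1: np.ndarray, t2: np.ndarray, n2: np.ndarray, pts: list):
    """Clip each edge of t1 against the plane of t2, keep points inside t2."""
    lo2, hi2 = t2.min(axis=0), t2.max(axis=0)
    for k in range(3):
        p, q = t1[k], t1[(k + 1) % 3]
        # quick reject against t2's axis-aligned bounding box
        if np.any(np.maximum(np.minimum(p, q), lo2) > np.minimum(np.maximum(p, q), hi2) + 1e-12):
            continue
        denom = n2 @ (q - p)
        if abs(denom) < 1e-300:
            continue
        t = (n2 @ (t2[0] - p)) / denom
        if t < -1e-12 or t > 1 + 1e-12:
            continue
        x = p + np.clip(t, 0.0, 1.0) * (q - p)
        if _inside_triangle(x, t2):
            pts.append(x)


def _segment_segment_2d(p1, q1, p2, q2, pts: list):
    """Coplanar edge-edge intersection in 3D (segments assumed coplanar)."""
    d1, d2 = q1 - p1, q2 - p2
    n = np.cross(d1, d2)
    nn = n @ n
    if nn < 1e-300:
        return
    r = p2 - p1
    t = np.cross(r, d2) @ n / nn
    s = np.cross(r, d1) @ n / nn
    if -1e-12 <= t <= 1 + 1e-12 and -1e-12 <= s <= 1 + 1e-12:
        pts.append(p1 + np.clip(t, 0.0, 1.0) * d1)


def triangle_pair_intersection(t1: np.ndarray, t2: np.ndarray) -> np.ndarray:
    """Distinct intersection points of two triangles (0, 1 or 2 points).

    Edge-based routine run symmetrically; coplanar overlapping pairs fall
    back to pairwise edge-edge intersection.
    """
    n1 = np.cross(t1[1] - t1[0], t1[2] - t1[0])
    n2 = np.cross(t2[1] - t2[0], t2[2] - t2[0])
    l1, l2 = np.linalg.norm(n1), np.linalg.norm(n2)
    if l1 == 0 or l2 == 0:
        return np.empty((0, 3))
    u1, u2 = n1 / l1, n2 / l2
    pts: list[np.ndarray] = []
    coplanar = (
        1 - abs(u1 @ u2) < COPLANAR_EPS
        and abs(u1 @ (t2[0] - t1[0])) < COPLANAR_EPS * max(1.0, np.abs(t1).max())
    )
    if coplanar:
        for i in range(3):
            for j in range(3):
                _segment_segment_2d(
                    t1[i], t1[(i + 1) % 3], t2[j], t2[(j + 1) % 3], pts
                )
    else:
        _edges_vs_triangle(t1, t2, n2, pts)
        _edges_vs_triangle(t2, t1, n1, pts)
    if not pts:
        return np.empty((0, 3))
    uniq: list[np.ndarray] = []
    for p in pts:
        if all(np.linalg.norm(p - q) > 1e-9 for q in uniq):
            uniq.append(p)
    return np.asarray(uniq)


# ---------------------------------------------------------------------------
# collision detection
# ---------------------------------------------------------------------------


@dataclass
class CollisionResult:
    """Intersection segments and the marked (intersecting) triangles."""

    segments: list[tuple[np.ndarray, np.ndarray]]
    segment_faces: list[tuple[int, int]]
    marked_a: set[int]
    marked_b: set[int]

    @property
    def points(self) -> np.ndarray:
        if not self.segments:
            return np.empty((0, 3))
        return np.asarray([p for seg in self.segments for p in seg])

    def __bool__(self) -> bool:
        return bool(self.segments)


def detect_collisions(
    a: TriangleMesh,
    b: TriangleMesh,
    tree_a: ObbTree | None = None,
    tree_b: ObbTree | None = None,
) -> CollisionResult:
    """All triangle-triangle intersections between two meshes (OBB pruned)."""
    tree_a = tree_a or build_obb_tree(a)
    tree_b = tree_b or build_obb_tree(b)
    leaf_pairs: list[tuple[np.ndarray, np.ndarray]] = []
    _leaf_pairs(tree_a.root, tree_b.root, leaf_pairs)
    pairs: set[tuple[int, int]] = set()
    for ia, ib in leaf_pairs:
        for fa in ia:
            for fb in ib:
                pairs.add((int(fa), int(fb)))
    return _collide_pairs(a, b, sorted(pairs))


def _collide_pairs(
    a: TriangleMesh, b: TriangleMesh, pairs
) -> CollisionResult:
    tri_a, tri_b = a.triangles, b.triangles
    segments, seg_faces = [], []
    marked_a: set[int] = set()
    marked_b: set[int] = set()
    for fa, fb in pairs:
        pts = triangle_pair_intersection(tri_a[fa], tri_b[fb])
        if len(pts) >= 2 and np.linalg.norm(pts[0] - pts[1]) > 1e-9:
            segments.append((pts[0], pts[1]))
            seg_faces.append((fa, fb))
            marked_a.add(fa)
            marked_b.add(fb)
    return CollisionResult(segments, seg_faces, marked_a, marked_b)


def detect_collisions_brute_force(a: TriangleMesh, b: TriangleMesh) -> CollisionResult:
    """All-pairs oracle (vectorised AABB prefilter, identical pair test)."""
    ta, tb = a.triangles, b.triangles
    lo_a, hi_a = ta.min(axis=1), ta.max(axis=1)
    lo_b, hi_b = tb.min(axis=1), tb.max(axis=1)
    overlap = np.all(
        (lo_a[:, None, :] <= hi_b[None, :, :] + 1e-12)
        & (lo_b[None, :, :] <= hi_a[:, None, :] + 1e-12),
        axis=2,
    )
    pairs = [tuple(map(int, p)) for p in np.argwhere(overlap)]
    return _collide_pairs(a, b, pairs)


# ---------------------------------------------------------------------------
# polylines
# ---------------------------------------------------------------------------


def extract_intersection_polylines(
    result: CollisionResult, tol: float = CHAIN_TOL
) -> list[tuple[np.ndarray, bool]]:
    """Chain per-pair segments into ordered polylines.

    Returns ``(points, closed)`` per polyline; an open chain (tangential,
    non-transversal contact) is returned with ``closed=False``.
    """
    if not result.segments:
        return []

    def key(p: np.ndarray) -> tuple[int, int, int]:
        return tuple(np.round(p / tol).astype(np.int64))

    # adjacency: endpoint key -> list of (segment index, end index)
    by_key: dict[tuple, list[tuple[int, int]]] = {}
    for si, (p0, p1) in enumerate(result.segments):
        by_key.setdefault(key(p0), []).append((si, 0))
        by_key.setdefault(key(p1), []).append((si, 1))

    used = [False] * len(result.segments)
    polylines: list[tuple[np.ndarray, bool]] = []
    for start in range(len(result.segments)):
        if used[start]:
            continue
        used[start] = True
        p0, p1 = result.segments[start]
        chain = [p0, p1]
        # extend forward from the tail, then backward from the head
        for end_of in (1, 0):
            while True:
                tip = chain[-1] if end_of == 1 else chain[0]
                candidates = [
                    (si, ei)
                    for si, ei in by_key.get(key(tip), [])
                    if not used[si]
                ]
                if not candidates:
                    break
                si, ei = candidates[0]
                used[si] = True
                nxt = result.segments[si][1 - ei]
                if end_of == 1:
                    chain.append(nxt)
                else:
                    chain.insert(0, nxt)
        closed = np.linalg.norm(chain[0] - chain[-1]) <= tol * 2
        pts = np.asarray(chain[:-1] if closed else chain)
        polylines.append((pts, closed))
    return polylines


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------


def _face_fragments(mesh: TriangleMesh, keep: np.ndarray) -> list[np.ndarray]:
    """Connected components (by shared edge) of the unmarked faces."""
    faces = np.nonzero(keep)[0]
    if len(faces) == 0:
        return []
    sub = mesh.faces[faces]
    edges = np.sort(
        np.concatenate([sub[:, [0, 1]], sub[:, [1, 2]], sub[:, [2, 0]]]), axis=1
    )
    owner = np.tile(np.arange(len(faces)), 3)
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    edges_s, owner_s = edges[order], owner[order]
    same = np.all(edges_s[1:] == edges_s[:-1], axis=1)
    rows = owner_s[:-1][same]
    cols = owner_s[1:][same]
    graph = coo_matrix(
        (np.ones(2 * len(rows)), (np.r_[rows, cols], np.r_[cols, rows])),
        shape=(len(faces), len(faces)),
    )
    n_comp, labels = connected_components(graph, directed=False)
    return [faces[labels == c] for c in range(n_comp)]


def _fragment_sample_point(mesh: TriangleMesh, frag_faces: np.ndarray) -> np.ndarray:
    tri = mesh.triangles[frag_faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    return tri[int(np.argmax(areas))].mean(axis=0)


def merge_union(
    a: TriangleMesh,
    b: TriangleMesh,
    result: CollisionResult | None = None,
) -> TriangleMesh:
    """Union-style merge of two intersecting surfaces.

    Marked triangles are removed, fragments inside the other closed mesh are
    discarded, and each kept ragged boundary is sealed to its intersection
    polyline with a ruled seam.  Raises :class:`MergeError` when the meshes
    do not collide (simple concatenation applies) or the contact is
    tangential (open polyline).
    """
    result = result if result is not None else detect_collisions(a, b)
    if not result:
        raise MergeError(
            "no collision between the meshes; use plain concatenation instead"
        )
    polylines = extract_intersection_polylines(result)
    open_count = sum(1 for _, closed in polylines if not closed)
    if open_count:
        raise MergeError(
            f"{open_count} open intersection polyline(s): tangential contact "
            "is not supported"
        )
    loops_pts = [pts for pts, _ in polylines]
    perims = [_perimeter(pl) for pl in loops_pts]
    usage = [0] * len(loops_pts)

    was_closed = check_closed(a)[0] and check_closed(b)[0]
    pieces: list[TriangleMesh] = []
    for mesh, other, marked in ((a, b, result.marked_a), (b, a, result.marked_b)):
        keep = np.ones(mesh.n_faces, dtype=bool)
        keep[sorted(marked)] = False
        max_edge = _max_edge_length(mesh)
        for frag in _face_fragments(mesh, keep):
            sample = _fragment_sample_point(mesh, frag)
            if point_in_mesh(sample, other):
                continue  # inside the other solid: swallowed by the union
            frag_mesh = TriangleMesh(mesh.vertices, mesh.faces[frag])
            matches: list[int | None] = []
            frag_loops = ordered_boundary_loops(frag_mesh)
            for loop in frag_loops:
                loop_pts = mesh.vertices[loop]
                dists = [
                    float(np.mean(_min_dist_to_points(loop_pts, pl)))
                    for pl in loops_pts
                ]
                if min(dists) > 3.0 * max_edge:
                    matches.append(None)  # an original open border, not a cut
                    continue
                # proximity plus perimeter similarity disambiguates concentric cuts
                per = _perimeter(loop_pts)
                scores = [d + 0.5 * abs(per - pp) for d, pp in zip(dists, perims)]
                matches.append(int(np.argmin(scores)))
            cut_ids = {j for j in matches if j is not None}
            if len(cut_ids) == 1:
                # a fragment bounded only by one cut circle and not larger than
                # its disk is a remnant of the surface the cut erased: drop it,
                # the fan cap over that polyline will seal the union instead
                (j,) = cut_ids
                if frag_mesh.area() <= 1.5 * _fan_cap(loops_pts[j]).area():
                    continue
            pieces.append(frag_mesh)
            for loop, j in zip(frag_loops, matches):
                if j is None:
                    continue
                usage[j] += 1
                pieces.append(
                    stitch_loops(
                        LoopPair(mesh.vertices[loop], loops_pts[j]),
                        closed=True,
                        auto_reverse=True,
                    )
                )
    # a cut circle smaller than the local triangles can erase the surface
    # patch it crossed; cap such polylines with a centroid fan so the union
    # still closes (each closed polyline must be sealed from both sides)
    for j, pl in enumerate(loops_pts):
        while usage[j] < 2:
            log.warning(
                "merge_union: polyline %d (%d points) used %d time(s); adding a fan cap",
                j, len(pl), usage[j],
            )
            pieces.append(_fan_cap(pl))
            usage[j] += 1
    merged = concatenate(pieces, weld_tol=1e-9)
    if was_closed:
        closed, loops = check_closed(merged)
        if not closed:
            raise MergeError(
                f"union of closed inputs is not closed: {len(loops)} boundary "
                f"loops remain (first loop has {len(loops[0])} vertices)"
            )
    return merged


def _perimeter(loop_pts: np.ndarray) -> float:
    return float(np.linalg.norm(np.roll(loop_pts, -1, axis=0) - loop_pts, axis=1).sum())


def _fan_cap(loop_pts: np.ndarray) -> TriangleMesh:
    """Triangle fan from the loop's centroid: a disk sealing the polyline."""
    center = loop_pts.mean(axis=0)
    n = len(loop_pts)
    vertices = np.concatenate([loop_pts, center[None]])
    faces = np.asarray([(i, (i + 1) % n, n) for i in range(n)], dtype=np.int64)
    return TriangleMesh(vertices, faces)


def _max_edge_length(mesh: TriangleMesh) -> float:
    tri = mesh.triangles
    e = np.linalg.norm(np.roll(tri, -1, axis=1) - tri, axis=2)
    return float(e.max())


def _min_dist_to_points(pts: np.ndarray, ref: np.ndarray) -> np.ndarray:
    from scipy.spatial import cKDTree

    return cKDTree(ref).query(pts)[0]
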