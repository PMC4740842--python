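"""Mesh segmentation along a point loop using signed per-vertex distances.

The template's tissue-contacting (inner) surface is cut out of the anatomy
mesh in three steps:

1. *Edge-loop tracking*: the loop points are snapped to their closest mesh
   vertices (anchors) and a cycle strictly along mesh edges is traced between
   consecutive anchors.  From the current vertex ``P`` the next vertex is the
   neighbor ``B`` that lies within 90 degrees of the anchor-to-anchor
   direction and is closest (perpendicular distance) to the anchor line; when
   no neighbor qualifies the walk falls back to a Dijkstra shortest path
   along the edges.
2. *Signed distances*: every vertex receives the unsigned minimum distance to
   the loop polyline's segments.  Removing the edge-loop vertices splits the
   mesh into components; the component nearest a caller-supplied hint point
   is positive, the rest negative.  Edge-loop vertices are signed from their
   largest-scalar off-loop neighbor ``N`` by comparing ``|NP|`` with ``|NQ|``
   (``Q`` the closest polyline point to ``P``).
3. *Clipping*: the signed field's zero level set cuts the triangles.  A
   triangle with mixed vertex signs is split in three by the two
   zero-crossing points, interpolated at ``t = |s_a| / (|s_a| + |s_b|)``
   along each sign-changing edge; crossing points are deduplicated per edge
   so the cut border is a crack-free polyline.

The whole pass is O(N*n) for N mesh vertices and an n-point loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import cKDTree

from .loop_input import ControlLoop, SurfaceLoop, densify_loop
from .mesh_core import AdjacencyMap, TriangleMesh, build_adjacency

MAX_WALK_STEPS = 200  # per anchor pair, before the shortest-path fallback


class SegmentationError(ValueError):
    """Raised when the loop cannot partition the mesh."""


@dataclass
class EdgeLoop:
    """Closed cycle of mesh-vertex indices running strictly along mesh edges."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.vertices)


@dataclass
class SignedScalarField:
    """Per-vertex signed distance (mm) to the cutting polyline."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)


# ---------------------------------------------------------------------------
# point-to-polyline distance
# ---------------------------------------------------------------------------


def point_to_polyline(points: np.ndarray, polyline: np.ndarray):
    """Min distance from each point to a closed polyline's segments.

    Returns ``(distances, closest_points)``.  Written with explicit component
    arithmetic so a scalar re-implementation reproduces it bit for bit.
    """
    p = np.atleast_2d(np.asarray(points, dtype=np.float64))
    a = np.asarray(polyline, dtype=np.float64)
    b = np.roll(a, -1, axis=0)
    dx, dy, dz = (b - a).T
    dd = dx * dx + dy * dy + dz * dz
    dd = np.where(dd == 0, 1.0, dd)

    best_d = np.full(len(p), np.inf)
    best_c = np.zeros_like(p)
    for s in range(len(a)):
        wx = p[:, 0] - a[s, 0]
        wy = p[:, 1] - a[s, 1]
        wz = p[:, 2] - a[s, 2]
        t = (wx * dx[s] + wy * dy[s] + wz * dz[s]) / dd[s]
        t = np.clip(t, 0.0, 1.0)
        ex = wx - t * dx[s]
        ey = wy - t * dy[s]
        ez = wz - t * dz[s]
        d = np.sqrt(ex * ex + ey * ey + ez * ez)
        closer = d < best_d
        best_d = np.where(closer, d, best_d)
        cx = a[s, 0] + t * dx[s]
        cy = a[s, 1] + t * dy[s]
        cz = a[s, 2] + t * dz[s]
        best_c[closer] = np.stack([cx, cy, cz], axis=1)[closer]
    return best_d, best_c


# ---------------------------------------------------------------------------
# edge loop tracking
# ---------------------------------------------------------------------------


def _point_line_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    d = b - a
    nn = d @ d
    if nn == 0:
        return float(np.linalg.norm(p - a))
    t = (p - a) @ d / nn
    return float(np.linalg.norm(p - (a + t * d)))


def _edge_graph(mesh: TriangleMesh, adjacency: AdjacencyMap):
    rows, cols, data = [], [], []
    for (u, w) in adjacency.edge_faces:
        d = float(np.linalg.norm(mesh.vertices[u] - mesh.vertices[w]))
        rows += [u, w]
        cols += [w, u]
        data += [d, d]
    n = mesh.n_vertices
    return coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()


def _dijkstra_path(graph, source: int, target: int) -> list[int]:
    dist, pred = dijkstra(graph, indices=source, return_predecessors=True)
    if not np.isfinite(dist[target]):
        raise SegmentationError(
            f"mesh is disconnected between loop anchors {source} and {target}"
        )
    path = [target]
    while path[-1] != source:
        path.append(int(pred[path[-1]]))
    return path[::-1]


def walk_candidate(
    vertices: np.ndarray,
    neighbors,
    p: int,
    a_i: int,
    a_next: int,
    visited: set[int],
) -> int | None:
    """The greedy step of edge-loop tracking: next vertex from ``p``.

    Among the unvisited neighbors of ``p`` within 90 degrees of the
    anchor-to-anchor direction, pick the one closest (perpendicular
    distance) to the anchor line; ties break toward the smaller index.
    Returns ``None`` when no neighbor qualifies (shortest-path fallback).
    """
    direction = vertices[a_next] - vertices[a_i]
    best, best_d = None, np.inf
    for b in sorted(neighbors):
        if b in visited:
            continue
        if (vertices[b] - vertices[p]) @ direction < 0:
            continue
        d = _point_line_distance(vertices[b], vertices[a_i], vertices[a_next])
        if d < best_d:
            best_d = d
            best = b
    return best


def track_edge_loop(
    loop: SurfaceLoop | ControlLoop | np.ndarray,
    mesh: TriangleMesh,
    adjacency: AdjacencyMap | None = None,
) -> EdgeLoop:
    """Trace a closed cycle of mesh vertices following the loop points.

    Implements the anchor-to-anchor greedy walk described in the module
    docstring, with a Dijkstra fallback when the walk stalls; ties on the
    perpendicular distance break toward the smaller vertex index.
    """
    pts = loop.points if hasattr(loop, "points") else np.atleast_2d(np.asarray(loop))
    adjacency = adjacency or build_adjacency(mesh)
    tree = cKDTree(mesh.vertices)
    anchors = tree.query(pts)[1].astype(np.int64)
    # collapse consecutive duplicate anchors
    keep = np.concatenate(([True], anchors[1:] != anchors[:-1]))
    anchors = anchors[keep]
    if len(anchors) > 1 and anchors[0] == anchors[-1]:
        anchors = anchors[:-1]
    if len(anchors) < 3:
        raise SegmentationError("loop collapses to fewer than 3 mesh vertices")

    graph = None
    verts = mesh.vertices
    out: list[int] = [int(anchors[0])]
    for i in range(len(anchors)):
        a_i = int(anchors[i])
        a_next = int(anchors[(i + 1) % len(anchors)])
        direction = verts[a_next] - verts[a_i]
        p = a_i
        visited = {p}
        steps = 0
        segment: list[int] = []
        while p != a_next:
            steps += 1
            best = None
            if steps <= MAX_WALK_STEPS:
                best = walk_candidate(
                    verts, adjacency.neighbors(p), p, a_i, a_next, visited
                )
            if best is None:
                if graph is None:
                    graph = _edge_graph(mesh, adjacency)
                segment = _dijkstra_path(graph, a_i, a_next)[1:]
                break
            segment.append(best)
            visited.add(best)
            p = best
        out.extend(segment)

    # drop the repeated closing anchor and prune revisit detours so the
    # cycle is simple (tracking across coarse loops can brush a vertex twice)
    if out and out[-1] == out[0]:
        out = out[:-1]
    seen: dict[int, int] = {}
    simple: list[int] = []
    for v in out:
        if v in seen:
            # cut the detour between the two visits
            pos = seen[v]
            for dropped in simple[pos + 1 :]:
                seen.pop(dropped, None)
            simple = simple[: pos + 1]
        else:
            seen[v] = len(simple)
            simple.append(v)
    if len(simple) < 3:
        raise SegmentationError("tracked edge loop degenerated to fewer than 3 vertices")
    for u, w in zip(simple, simple[1:] + simple[:1]):
        if w not in adjacency.neighbors(u):
            raise SegmentationError(f"tracked loop broke adjacency between {u} and {w}")
    return EdgeLoop(np.asarray(simple, dtype=np.int64))


# ---------------------------------------------------------------------------
# signed distances
# ---------------------------------------------------------------------------


def signed_vertex_distances(
    mesh: TriangleMesh,
    loop: SurfaceLoop | ControlLoop | np.ndarray,
    edge_loop: EdgeLoop,
    positive_side_hint: np.ndarray,
    adjacency: AdjacencyMap | None = None,
) -> SignedScalarField:
    """Signed min distance from every mesh vertex to the loop polyline.

    The side containing the vertex nearest ``positive_side_hint`` is positive.
    Raises :class:`SegmentationError` if removing the edge-loop vertices does
    not split the mesh (loop too sparse or tangled).
    """
    pts = loop.points if hasattr(loop, "points") else np.atleast_2d(np.asarray(loop))
    adjacency = adjacency or build_adjacency(mesh)
    unsigned, closest = point_to_polyline(mesh.vertices, pts)

    on_loop = np.zeros(mesh.n_vertices, dtype=bool)
    on_loop[edge_loop.vertices] = True

    # connected components of the mesh graph minus the loop vertices
    rows, cols = [], []
    for (u, w) in adjacency.edge_faces:
        if on_loop[u] or on_loop[w]:
            continue
        rows.append(u)
        cols.append(w)
    n = mesh.n_vertices
    graph = coo_matrix(
        (np.ones(2 * len(rows)), (rows + cols, cols + rows)), shape=(n, n)
    ).tocsr()
    n_comp, labels = connected_components(graph, directed=False)
    free = ~on_loop
    comp_ids = np.unique(labels[free])
    if len(comp_ids) < 2:
        raise SegmentationError(
            "edge loop does not separate the mesh (loop too sparse or tangled); "
            "densify the loop or add control points"
        )

    hint = np.asarray(positive_side_hint, dtype=np.float64)
    free_idx = np.nonzero(free)[0]
    d_hint = np.linalg.norm(mesh.vertices[free_idx] - hint, axis=1)
    pos_comp = labels[free_idx[int(np.argmin(d_hint))]]

    sign = np.where(labels == pos_comp, 1.0, -1.0)
    if len(comp_ids) > 2:
        # the two sides of the cut are the hint component and the largest
        # remaining one; tiny extra components are pockets pinched off by the
        # tracked loop and inherit the sign of their nearest main-side vertex
        sizes = {c: int(np.sum(labels[free] == c)) for c in comp_ids}
        neg_comp = max(
            (c for c in comp_ids if c != pos_comp), key=lambda c: (sizes[c], -c)
        )
        main = free & ((labels == pos_comp) | (labels == neg_comp))
        main_idx = np.nonzero(main)[0]
        tree = cKDTree(mesh.vertices[main_idx])
        for c in comp_ids:
            if c in (pos_comp, neg_comp):
                continue
            members = np.nonzero(free & (labels == c))[0]
            nearest = main_idx[tree.query(mesh.vertices[members])[1]]
            majority = np.sign(np.where(labels[nearest] == pos_comp, 1.0, -1.0).sum())
            sign[members] = majority if majority != 0 else 1.0
    sign[on_loop] = 0.0

    # loop vertices: where the off-loop neighbors agree on a side the vertex
    # lies strictly on that side (the tracked loop wanders off the polyline);
    # only in mixed neighborhoods — at the actual crossing — is the sign
    # taken from the largest-scalar neighbor N by comparing |NP| with |NQ|
    # (Q = closest polyline point to P)
    for v in edge_loop.vertices:
        v = int(v)
        neigh = [b for b in adjacency.neighbors(v) if not on_loop[b]]
        if not neigh:
            sign[v] = 1.0
            continue
        neigh_signs = {sign[b] for b in neigh}
        if len(neigh_signs) == 1:
            sign[v] = neigh_signs.pop()
            continue
        n_i = max(neigh, key=lambda b: (unsigned[b], -b))
        np_dist = np.linalg.norm(mesh.vertices[n_i] - mesh.vertices[v])
        nq_dist = np.linalg.norm(mesh.vertices[n_i] - closest[v])
        s_n = sign[n_i] if sign[n_i] != 0 else 1.0
        sign[v] = s_n if np_dist < nq_dist else -s_n

    return SignedScalarField(unsigned * sign)


# ---------------------------------------------------------------------------
# clipping
# ---------------------------------------------------------------------------


def clip_by_scalar(
    mesh: TriangleMesh, field: SignedScalarField, keep: str = "positive"
) -> TriangleMesh:
    """Cut the mesh along the field's zero level set and keep one side.

    Vertices with scalar exactly 0 count as positive.  Mixed-sign triangles
    are split in three by linearly interpolated zero-crossing points; crossing
    points are shared across neighboring triangles via their edge key so the
    cut boundary is a connected, crack-free polyline.
    """
    if keep not in ("positive", "negative"):
        raise ValueError("keep must be 'positive' or 'negative'")
    s = field.values
    if len(s) != mesh.n_vertices:
        raise ValueError("field length does not match vertex count")
    pos = s >= 0.0
    want = pos if keep == "positive" else ~pos

    face_pos = pos[mesh.faces]
    n_pos = face_pos.sum(axis=1)
    uniform = (n_pos == 0) | (n_pos == 3)
    keep_uniform = mesh.faces[uniform & (want[mesh.faces].all(axis=1))]

    new_vertices = [mesh.vertices]
    next_idx = mesh.n_vertices
    edge_cut: dict[tuple[int, int], int] = {}
    out_faces: list[tuple[int, int, int]] = []
    out_faces.extend(map(tuple, keep_uniform))

    def cut_vertex(a: int, b: int) -> int:
        nonlocal next_idx
        key = (a, b) if a < b else (b, a)
        idx = edge_cut.get(key)
        if idx is None:
            sa, sb = abs(s[a]), abs(s[b])
            t = sa / (sa + sb)
            new_vertices.append((mesh.vertices[a] + t * (mesh.vertices[b] - mesh.vertices[a]))[None])
            idx = next_idx
            edge_cut[key] = idx
            next_idx += 1
        return idx

    for f in mesh.faces[~uniform]:
        fa, fb, fc = (int(x) for x in f)
        # rotate so the lone-sign vertex is first
        for _ in range(3):
            if pos[fa] != pos[fb] and pos[fa] != pos[fc]:
                break
            fa, fb, fc = fb, fc, fa
        zab = cut_vertex(fa, fb)
        zca = cut_vertex(fc, fa)
        lone_kept = want[fa]
        if lone_kept:
            out_faces.append((fa, zab, zca))
        else:
            out_faces.append((zab, fb, fc))
            out_faces.append((zab, fc, zca))

    vertices = np.concatenate(new_vertices)
    faces = np.asarray(out_faces, dtype=np.int64).reshape(-1, 3)
    used = np.unique(faces)
    remap = np.full(len(vertices), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriangleMesh(vertices[used], remap[faces])


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------


def segment_inner_surface(
    mesh: TriangleMesh,
    loop: ControlLoop | np.ndarray,
    positive_side_hint: np.ndarray,
    step: float = 1.0,
    adjacency: AdjacencyMap | None = None,
):
    """Densify the control loop, track, sign and clip: the inner surface.

    Returns ``(inner_mesh, dense_loop, field)``; the kept side is the one
    containing ``positive_side_hint``.
    """
    if not isinstance(loop, ControlLoop):
        loop = ControlLoop(np.asarray(loop))
    adjacency = adjacency or build_adjacency(mesh)
    dense = densify_loop(loop, mesh, step=step)
    edge_loop = track_edge_loop(dense, mesh, adjacency)
    field = signed_vertex_distances(mesh, dense, edge_loop, positive_side_hint, adjacency)
    inner = clip_by_scalar(mesh, field, keep="positive")
    return inner, dense, field
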