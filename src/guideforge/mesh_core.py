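"""Triangle-mesh data model, STL I/O and geometric kernels.

Everything downstream (segmentation, offsetting, stitching, booleans) speaks
:class:`TriangleMesh`: an indexed triangle soup in millimetres with 0-based
face indices, a right-handed frame and outward-facing CCW winding where the
mesh is orientable.  STL files carry no connectivity, so meshes are welded on
read (vertices coincident within ``WELD_TOL`` merged) before any adjacency is
built; the traversal algorithms assume a manifold mesh and non-manifold input
is rejected at read time.

The module also hosts the exact point/triangle proximity and ray-casting
kernels shared by the later stages: closest point on a triangle (Ericson's
region classification, vectorised), KD-tree-pruned exact point-to-mesh
distance, Moeller-Trumbore ray casting and ray-parity containment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import trimesh as _trimesh
from scipy.spatial import cKDTree

log = logging.getLogger("guideforge")

#: vertices closer than this (mm) are considered the same point on read.
WELD_TOL = 1e-6


class MeshError(ValueError):
    """Raised for malformed, empty or non-manifold meshes."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass
class TriangleMesh:
    """Indexed triangle mesh: ``vertices`` (V,3) float64 mm, ``faces`` (F,3) int."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be (F, 3)")
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise MeshError("face index out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def triangles(self) -> np.ndarray:
        """Face corner coordinates, shape (F, 3, 3)."""
        return self.vertices[self.faces]

    def face_normals(self, normalize: bool = True) -> np.ndarray:
        tri = self.triangles
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        if normalize:
            norm = np.linalg.norm(n, axis=1, keepdims=True)
            n = np.divide(n, norm, out=np.zeros_like(n), where=norm > 0)
        return n

    def face_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.face_normals(normalize=False), axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def signed_volume(self) -> float:
        """Divergence-theorem volume; meaningful for consistently wound closed meshes."""
        tri = self.triangles
        return float(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy())


@dataclass
class AdjacencyMap:
    """Vertex and edge adjacency of a welded mesh.

    ``vertex_neighbors[v]`` is the set of vertices sharing an edge with ``v``;
    ``edge_faces[(u, w)]`` (u < w) lists faces incident to the undirected edge.
    """

    vertex_neighbors: list[set[int]]
    edge_faces: dict[tuple[int, int], list[int]] = field(repr=False)

    def neighbors(self, v: int) -> set[int]:
        return self.vertex_neighbors[v]


def weld_vertices(
    vertices: np.ndarray, faces: np.ndarray, tol: float = WELD_TOL
) -> tuple[np.ndarray, np.ndarray]:
    """Merge vertices coincident within ``tol`` and drop degenerate faces."""
    vertices = np.asarray(vertices, dtype=np.float64)
    faces = np.asarray(faces, dtype=np.int64)
    keys = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    # preserve first-occurrence order for determinism
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    new_vertices = vertices[first[order]]
    new_faces = rank[inverse][faces]
    ok = (
        (new_faces[:, 0] != new_faces[:, 1])
        & (new_faces[:, 1] != new_faces[:, 2])
        & (new_faces[:, 2] != new_faces[:, 0])
    )
    return new_vertices, new_faces[ok]


def weld_mesh(mesh: TriangleMesh, tol: float = WELD_TOL) -> TriangleMesh:
    v, f = weld_vertices(mesh.vertices, mesh.faces, tol)
    return TriangleMesh(v, f)


# ---------------------------------------------------------------------------
# STL I/O
# ---------------------------------------------------------------------------


def read_stl(path, weld_tol: float = WELD_TOL, require_manifold: bool = True) -> TriangleMesh:
    """Read a binary or ASCII STL file into a welded :class:`TriangleMesh`.

    Facet winding is preserved.  Raises :class:`MeshError` on malformed files,
    empty meshes and (by default) non-manifold connectivity.
    """
    try:
        raw = _trimesh.load_mesh(str(path), file_type="stl", process=False)
    except Exception as exc:  # noqa: BLE001 - surface the codec's message
        raise MeshError(f"cannot parse STL file {path!s}: {exc}") from exc
    if isinstance(raw, _trimesh.Scene):
        geoms = list(raw.geometry.values())
        if not geoms:
            raise MeshError(f"empty STL file {path!s}")
        raw = _trimesh.util.concatenate(geoms)
    vertices = np.asarray(raw.vertices, dtype=np.float64)
    faces = np.asarray(raw.faces, dtype=np.int64)
    if len(faces) == 0:
        raise MeshError(f"empty STL file {path!s}")
    v, f = weld_vertices(vertices, faces, weld_tol)
    mesh = TriangleMesh(v, f)
    if require_manifold:
        bad = nonmanifold_edges(mesh)
        if bad:
            raise MeshError(
                f"non-manifold STL {path!s}: {len(bad)} edges with >2 incident faces "
                f"(first: {bad[0]})"
            )
    return mesh


def write_stl(mesh: TriangleMesh, path, mode: str = "binary") -> None:
    """Write ``mesh`` to ``path`` as ``binary`` or ``ascii`` STL."""
    if mesh.n_faces == 0:
        raise MeshError("refusing to write empty mesh")
    if mode not in ("binary", "ascii"):
        raise ValueError(f"mode must be 'binary' or 'ascii', got {mode!r}")
    tm = _trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    data = tm.export(file_type="stl_ascii" if mode == "ascii" else "stl")
    if isinstance(data, str):
        data = data.encode()
    with open(path, "wb") as fh:
        fh.write(data)


# ---------------------------------------------------------------------------
# adjacency and integrity
# ---------------------------------------------------------------------------


def build_adjacency(mesh: TriangleMesh) -> AdjacencyMap:
    """Vertex-neighbor sets and edge→face incidence for a welded mesh."""
    neighbors: list[set[int]] = [set() for _ in range(mesh.n_vertices)]
    edge_faces: dict[tuple[int, int], list[int]] = {}
    for fi, (a, b, c) in enumerate(mesh.faces):
        for u, w in ((a, b), (b, c), (c, a)):
            u, w = int(u), int(w)
            neighbors[u].add(w)
            neighbors[w].add(u)
            key = (u, w) if u < w else (w, u)
            edge_faces.setdefault(key, []).append(fi)
    return AdjacencyMap(neighbors, edge_faces)


def nonmanifold_edges(mesh: TriangleMesh) -> list[tuple[int, int]]:
    """Undirected edges incident to more than two faces."""
    e = np.sort(
        np.concatenate([mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]]),
        axis=1,
    )
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    return [tuple(map(int, row)) for row in uniq[counts > 2]]


def boundary_directed_edges(mesh: TriangleMesh) -> np.ndarray:
    """Directed boundary edges (tail, head) in face-winding order, shape (B, 2)."""
    directed = np.concatenate(
        [mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]]
    )
    und = np.sort(directed, axis=1)
    uniq, inverse, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
    return directed[counts[inverse] == 1]


def check_closed(mesh: TriangleMesh) -> tuple[bool, list[list[int]]]:
    """Whether every edge has exactly two incident faces.

    Returns ``(closed, boundary_loops)`` where each loop is an ordered list of
    vertex indices following face winding.  Non-manifold edges raise
    :class:`MeshError` — they are never silently reported as closed.
    """
    bad = nonmanifold_edges(mesh)
    if bad:
        raise MeshError(f"non-manifold mesh: {len(bad)} edges with >2 faces (first: {bad[0]})")
    edges = boundary_directed_edges(mesh)
    if len(edges) == 0:
        return True, []
    succ: dict[int, int] = {}
    for tail, head in edges:
        succ[int(tail)] = int(head)
    loops: list[list[int]] = []
    seen: set[int] = set()
    for start in sorted(succ):
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        cur = succ[start]
        while cur != start:
            loop.append(cur)
            seen.add(cur)
            if cur not in succ:  # open chain: boundary not a closed cycle
                break
            cur = succ[cur]
        loops.append(loop)
    return False, loops


def vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    """Area-weighted per-vertex unit normals; isolated vertices get zero vectors."""
    weighted = mesh.face_normals(normalize=False)  # = 2*area * unit normal
    out = np.zeros_like(mesh.vertices)
    for k in range(3):
        np.add.at(out, mesh.faces[:, k], weighted)
    norm = np.linalg.norm(out, axis=1, keepdims=True)
    zero = norm[:, 0] <= 0
    if zero.any():
        log.warning("vertex_normals: %d isolated/degenerate vertices flagged with zero normal",
                    int(zero.sum()))
    return np.divide(out, norm, out=np.zeros_like(out), where=norm > 0)


def orient_consistently(mesh: TriangleMesh, outward: bool = True) -> TriangleMesh:
    """Flip faces so adjacent faces traverse shared edges oppositely.

    For a closed mesh with ``outward=True`` the result is flipped globally, if
    needed, so the signed volume is positive.
    """
    adj = build_adjacency(mesh)
    faces = mesh.faces.copy()
    n_f = len(faces)
    face_edges = [
        [(int(f[0]), int(f[1])), (int(f[1]), int(f[2])), (int(f[2]), int(f[0]))]
        for f in faces
    ]
    visited = np.zeros(n_f, dtype=bool)
    for seed in range(n_f):
        if visited[seed]:
            continue
        stack = [seed]
        visited[seed] = True
        while stack:
            fi = stack.pop()
            for u, w in face_edges[fi]:
                key = (u, w) if u < w else (w, u)
                for fj in adj.edge_faces[key]:
                    if visited[fj]:
                        continue
                    # fj must traverse the shared edge as (w, u)
                    same_dir = (u, w) in face_edges[fj]
                    if same_dir:
                        faces[fj] = faces[fj][::-1]
                        face_edges[fj] = [
                            (int(faces[fj][0]), int(faces[fj][1])),
                            (int(faces[fj][1]), int(faces[fj][2])),
                            (int(faces[fj][2]), int(faces[fj][0])),
                        ]
                    visited[fj] = True
                    stack.append(fj)
    out = TriangleMesh(mesh.vertices.copy(), faces)
    if outward and out.signed_volume() < 0:
        out.faces = out.faces[:, ::-1]
    return out


def concatenate(meshes: list[TriangleMesh], weld_tol: float = 1e-9) -> TriangleMesh:
    """Concatenate meshes and weld coincident vertices across them."""
    offs = 0
    vs, fs = [], []
    for m in meshes:
        vs.append(m.vertices)
        fs.append(m.faces + offs)
        offs += m.n_vertices
    v, f = weld_vertices(np.concatenate(vs), np.concatenate(fs), weld_tol)
    return TriangleMesh(v, f)


# ---------------------------------------------------------------------------
# proximity kernels
# ---------------------------------------------------------------------------


def closest_point_on_triangles(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Closest point on triangle i to point i (vectorised region classification).

    ``points`` is (N,3), ``triangles`` is (N,3,3); returns (N,3).
    """
    p = np.asarray(points, dtype=np.float64)
    a, b, c = triangles[:, 0], triangles[:, 1], triangles[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def take(mask, value):
        nonlocal done
        m = mask & ~done
        out[m] = value[m]
        done = done | m

    take((d1 <= 0) & (d2 <= 0), a)
    take((d3 >= 0) & (d4 <= d3), b)
    take((d6 >= 0) & (d5 <= d6), c)

    vc = d1 * d4 - d3 * d2
    t = np.divide(d1, d1 - d3, out=np.zeros_like(d1), where=(d1 - d3) != 0)
    take((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + t[:, None] * ab)
    vb = d5 * d2 - d1 * d6
    t = np.divide(d2, d2 - d6, out=np.zeros_like(d2), where=(d2 - d6) != 0)
    take((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + t[:, None] * ac)
    va = d3 * d6 - d5 * d4
    denom = (d4 - d3) + (d5 - d6)
    t = np.divide(d4 - d3, denom, out=np.zeros_like(denom), where=denom != 0)
    take((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + t[:, None] * (c - b))

    s = va + vb + vc
    inv = np.divide(1.0, s, out=np.zeros_like(s), where=s != 0)
    v = vb * inv
    w = vc * inv
    take(np.ones(len(p), dtype=bool), a + v[:, None] * ab + w[:, None] * ac)
    return out


class MeshProximity:
    """KD-tree-pruned exact closest-point queries against a triangle mesh.

    Candidate triangles are gathered from a KD tree over triangle centroids
    using a per-query radius derived from the nearest-vertex distance, which
    guarantees the true closest triangle is always among the candidates — the
    returned distances are exact, equal to a brute-force scan over all faces.
    """

    def __init__(self, mesh: TriangleMesh):
        if mesh.n_faces == 0:
            raise MeshError("proximity query against empty mesh")
        self.mesh = mesh
        tri = mesh.triangles
        self._centroids = tri.mean(axis=1)
        self._radii = np.linalg.norm(tri - self._centroids[:, None, :], axis=2).max(axis=1)
        self._rmax = float(self._radii.max())
        self._vtree = cKDTree(mesh.vertices)
        self._ctree = cKDTree(self._centroids)

    def query(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (distances, closest_points, face_indices) for ``points`` (N,3)."""
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        upper, _ = self._vtree.query(points, workers=-1)
        radii = upper + self._rmax + 1e-12
        cand = self._ctree.query_ball_point(points, radii, workers=-1)
        pt_idx = np.concatenate(
            [np.full(len(c), i, dtype=np.int64) for i, c in enumerate(cand)]
        )
        tri_idx = np.concatenate([np.asarray(c, dtype=np.int64) for c in cand])
        closest = closest_point_on_triangles(
            points[pt_idx], self.mesh.triangles[tri_idx]
        )
        d = np.linalg.norm(points[pt_idx] - closest, axis=1)
        # first occurrence per point after sorting by (point, distance, face)
        order = np.lexsort((tri_idx, d, pt_idx))
        first = np.unique(pt_idx[order], return_index=True)[1]
        sel = order[first]
        return d[sel], closest[sel], tri_idx[sel]


# ---------------------------------------------------------------------------
# ray casting
# ---------------------------------------------------------------------------


def ray_mesh_hits(
    origin: np.ndarray, direction: np.ndarray, mesh: TriangleMesh, eps: float = 1e-12
) -> tuple[np.ndarray, np.ndarray]:
    """All ray/triangle hits (Moeller-Trumbore): returns (t values, face indices).

    Hits are sorted by ``t``; only ``t > eps`` forward hits are returned.
    """
    origin = np.asarray(origin, dtype=np.float64)
    d = np.asarray(direction, dtype=np.float64)
    tri = mesh.triangles
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    pvec = np.cross(d, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > eps
    inv = np.divide(1.0, det, out=np.zeros_like(det), where=ok)
    tvec = origin - tri[:, 0]
    u = np.einsum("ij,ij->i", tvec, pvec) * inv
    qvec = np.cross(tvec, e1)
    v = np.einsum("j,ij->i", d, qvec) * inv
    t = np.einsum("ij,ij->i", e2, qvec) * inv
    hit = ok & (u >= -1e-12) & (v >= -1e-12) & (u + v <= 1 + 1e-12) & (t > eps)
    faces = np.nonzero(hit)[0]
    ts = t[hit]
    order = np.argsort(ts)
    return ts[order], faces[order]


_PARITY_DIR = np.array([0.57735026, 0.57735027, 0.57735028])


def point_in_mesh(point: np.ndarray, mesh: TriangleMesh) -> bool:
    """Ray-parity containment test against a closed mesh."""
    ts, _ = ray_mesh_hits(point, _PARITY_DIR, mesh)
    # collapse numerically duplicate hits (ray grazing a shared edge)
    if len(ts) > 1:
        ts = ts[np.concatenate(([True], np.diff(ts) > 1e-9))]
    return len(ts) % 2 == 1
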