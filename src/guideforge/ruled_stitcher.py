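"""Ruled-surface stitching of two ordered point loops.

The template's side wall (and every boolean seam) is a triangle strip
between two closed contours ``p = P_0..P_{m-1}`` and ``q = Q_0..Q_{n-1}``.
Every strip triangle uses one contour segment and two spans ``P_iQ_j``; the
non-crossing condition forces span indices to be monotone, so a strip is a
monotone staircase path through the (m x n) grid of spans and the handled
contours contribute m + n - 2 triangles when treated as open chains.

The strip that minimises total span length is found with a label-setting
dynamic program over the directed single-layer span graph: node ``V_{i,j}``
is span ``P_iQ_j``, arcs go right/up, the weight of the arcs *into* a node is
that node's span length, and each node keeps ``(i, j, length, Dis, Prev)``
with ``Dis`` the shortest distance from ``V_{0,0}``.  On this DAG the label
setting is equal to Dijkstra — asserted as a test property.

``closed=True`` adds the two seam triangles over the wrap segments
``P_{m-1}P_0`` and ``Q_{n-1}Q_0`` so a stitched shell can be watertight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh_core import TriangleMesh, boundary_directed_edges


class StitchError(ValueError):
    """Raised for degenerate or inconsistently wound loop pairs."""


@dataclass
class LoopPair:
    """Two ordered closed loops to be stitched, aligned and co-wound.

    ``align`` rotates ``q`` so its point closest to ``P_0`` becomes ``Q_0``
    (ties to the smaller index).  ``auto_reverse`` flips ``q`` when the
    projected signed areas of the loops disagree; with it off a winding
    mismatch raises :class:`StitchError` telling the caller to reverse.
    """

    p: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.atleast_2d(np.asarray(self.p, dtype=np.float64))
        self.q = np.atleast_2d(np.asarray(self.q, dtype=np.float64))
        if len(self.p) < 2 or len(self.q) < 2:
            raise StitchError("both loops need at least 2 points")

    @property
    def m(self) -> int:
        return len(self.p)

    @property
    def n(self) -> int:
        return len(self.q)

    def prepared(self, align: bool = True, auto_reverse: bool = False) -> "LoopPair":
        q = self.q
        if not _same_winding(self.p, q):
            if not auto_reverse:
                raise StitchError(
                    "loops have opposite winding; reverse one loop or pass "
                    "auto_reverse=True"
                )
            q = q[::-1]
        if align:
            j0 = int(np.argmin(np.linalg.norm(q - self.p[0], axis=1)))
            q = np.roll(q, -j0, axis=0)
        return LoopPair(self.p, q)


def _same_winding(p: np.ndarray, q: np.ndarray) -> bool:
    """Compare loop windings via signed areas projected on the common best-fit plane."""
    allpts = np.concatenate([p, q])
    center = allpts.mean(axis=0)
    u, s, vt = np.linalg.svd(allpts - center, full_matrices=False)
    normal = vt[2]
    e1, e2 = vt[0], vt[1]

    def signed_area(loop):
        x = (loop - center) @ e1
        y = (loop - center) @ e2
        return 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)

    ap, aq = signed_area(p), signed_area(q)
    if ap == 0 or aq == 0:  # degenerate loop (e.g. repeated point): treat as matched
        return True
    return (ap > 0) == (aq > 0)


@dataclass
class SpanPath:
    """Monotone node path V_{0,0}..V_{m-1,n-1} and the DP labels."""

    nodes: list[tuple[int, int]]
    total_cost: float
    dis: np.ndarray
    prev: np.ndarray


def span_graph_shortest_path(pair: LoopPair) -> SpanPath:
    """Two-phase label setting on the span grid, exactly as specified.

    Row 0 / Column 0 first (their predecessor is forced), then the double
    loop comparing ``Dis_{i-1,j}`` with ``Dis_{i,j-1}`` under strict ``<``
    (ties take the ``else`` branch, Prev = +1, i.e. the left predecessor).
    """
    p, q = pair.p, pair.q
    m, n = pair.m, pair.n
    length = np.linalg.norm(p[:, None, :] - q[None, :, :], axis=2)  # |P_i Q_j|
    dis = np.zeros((m, n))
    prev = np.zeros((m, n), dtype=np.int8)  # +1 from left (j-1), -1 from below (i-1)
    for j in range(1, n):
        dis[0, j] = dis[0, j - 1] + length[0, j]
        prev[0, j] = 1
    for i in range(1, m):
        dis[i, 0] = dis[i - 1, 0] + length[i, 0]
        prev[i, 0] = -1
    for i in range(1, m):
        for j in range(1, n):
            if dis[i - 1, j] < dis[i, j - 1]:
                dis[i, j] = dis[i - 1, j] + length[i, j]
                prev[i, j] = -1
            else:
                dis[i, j] = dis[i, j - 1] + length[i, j]
                prev[i, j] = 1
    nodes = [(m - 1, n - 1)]
    while nodes[-1] != (0, 0):
        i, j = nodes[-1]
        nodes.append((i - 1, j) if prev[i, j] == -1 else (i, j - 1))
    nodes.reverse()
    return SpanPath(nodes, float(dis[m - 1, n - 1]), dis, prev)


def stitch_loops(
    pair: LoopPair,
    closed: bool = False,
    align: bool = True,
    auto_reverse: bool = False,
) -> TriangleMesh:
    """Triangle strip between the two loops along the shortest span path.

    Open mode emits exactly ``m + n - 2`` triangles; ``closed`` adds the two
    wrap-seam triangles (``m + n`` total) so the joined shell can close up.
    Strip vertices are exactly the ``m + n`` loop points: ``P_i`` at index
    ``i`` and ``Q_j`` at index ``m + j``.
    """
    pair = pair.prepared(align=align, auto_reverse=auto_reverse)
    m, n = pair.m, pair.n
    path = span_graph_shortest_path(pair)
    faces: list[tuple[int, int, int]] = []
    for (i0, j0), (i1, j1) in zip(path.nodes[:-1], path.nodes[1:]):
        if i1 == i0 + 1:  # P-step: contour segment P_i0 P_i1, apex Q_j0
            faces.append((i0, i1, m + j0))
        else:  # Q-step: contour segment Q_j0 Q_j1, apex P_i0
            faces.append((m + j1, m + j0, i0))
    if closed:
        # seam quad P_{m-1} P_0 Q_{n-1} Q_0, split by the shorter diagonal
        d1 = np.linalg.norm(pair.p[m - 1] - pair.q[0])
        d2 = np.linalg.norm(pair.p[0] - pair.q[n - 1])
        if d1 <= d2:
            faces.append((m - 1, 0, m + 0))
            faces.append((m + 0, m + n - 1, m - 1))
        else:
            faces.append((m - 1, 0, m + n - 1))
            faces.append((0, m + 0, m + n - 1))
    vertices = np.concatenate([pair.p, pair.q])
    return TriangleMesh(vertices, np.asarray(faces, dtype=np.int64))


def ordered_boundary_loops(mesh: TriangleMesh) -> list[np.ndarray]:
    """All boundary loops of an open mesh as ordered vertex-index arrays.

    Orientation follows face winding.  A closed mesh yields an empty list;
    a non-manifold boundary (a vertex with more than one outgoing boundary
    edge) raises :class:`StitchError`.
    """
    edges = boundary_directed_edges(mesh)
    if len(edges) == 0:
        return []
    succ: dict[int, int] = {}
    for tail, head in edges:
        tail, head = int(tail), int(head)
        if tail in succ:
            raise StitchError(f"non-manifold boundary at vertex {tail}")
        succ[tail] = head
    loops = []
    seen: set[int] = set()
    for start in sorted(succ):
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        cur = succ.get(start)
        while cur is not None and cur != start:
            loop.append(cur)
            seen.add(cur)
            cur = succ.get(cur)
        if cur != start:
            raise StitchError("boundary chain does not close into a loop")
        loops.append(np.asarray(loop, dtype=np.int64))
    return loops


def ordered_boundary_loop(mesh: TriangleMesh) -> np.ndarray:
    """The single boundary loop of an open mesh (error if there are several)."""
    loops = ordered_boundary_loops(mesh)
    if len(loops) != 1:
        raise StitchError(f"expected exactly one boundary loop, found {len(loops)}")
    return loops[0]
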