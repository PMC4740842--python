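"""OBB trees, triangle-pair intersections, polylines, and union merging."""

import numpy as np
import pytest

from guideforge import (
    TriangleMesh,
    build_obb_tree,
    check_closed,
    detect_collisions,
    extract_intersection_polylines,
    merge_union,
)
from guideforge.boolean_merge import (
    MergeError,
    detect_collisions_brute_force,
    obb_overlap,
    triangle_pair_intersection,
)
from guideforge.fixtures import make_ridge, make_sphere
from guideforge.mesh_core import orient_consistently
from guideforge.pipeline import design_template
from guideforge.tube_builder import TubeSpec, make_tube


def translated(mesh, offset):
    return TriangleMesh(mesh.vertices + np.asarray(offset, float), mesh.faces)


class TestObbTree:
    def test_single_triangle_is_one_leaf(self):
        tri = TriangleMesh(np.eye(3), np.array([[0, 1, 2]]))
        tree = build_obb_tree(tri)
        assert tree.root.is_leaf
        assert list(tree.root.tri_indices) == [0]

    def test_leaves_contain_their_triangles(self):
        sphere = make_sphere(1.0, 2)
        tree = build_obb_tree(sphere, leaf_size=8)

        def check(node):
            if node.is_leaf:
                corners = sphere.triangles[node.tri_indices].reshape(-1, 3)
                local = np.abs((corners - node.center) @ node.axes.T)
                assert np.all(local <= node.half + 1e-9)
            else:
                check(node.children[0])
                check(node.children[1])

        check(tree.root)

    def test_elongated_cylinder_root_axis(self):
        spec = TubeSpec(
            origin=(0, 0, 0), direction=(0, 0, 1),
            inner_radius_mm=0.5, outer_radius_mm=1.0, length_mm=30.0,
        )
        tube = make_tube(spec)
        tree = build_obb_tree(tube)
        # principal box axis within 15 degrees of the cylinder axis
        cosang = abs(tree.root.axes[0] @ np.array([0.0, 0.0, 1.0]))
        assert cosang >= np.cos(np.deg2rad(15))

    def test_depth_bound(self):
        sphere = make_sphere(1.0, 3)  # 1280 faces
        tree = build_obb_tree(sphere, leaf_size=8)
        assert tree.depth <= int(np.ceil(np.log2(1280 / 8))) + 2

    def test_disjoint_roots_reject(self):
        a = build_obb_tree(make_sphere(1.0, 1)).root
        b = build_obb_tree(translated(make_sphere(1.0, 1), [10, 0, 0])).root
        assert not obb_overlap(a, b)


class TestTrianglePairIntersection:
    def test_transversal_crossing_two_points(self):
        t1 = np.array([[0.0, -1.0, 0.0], [2.0, -1.0, 0.0], [0.0, 2.0, 0.0]])
        t2 = np.array([[0.5, 0.0, -1.0], [0.5, 0.0, 1.0], [0.5, 2.0, 0.0]])
        pts = triangle_pair_intersection(t1, t2)
        assert len(pts) == 2
        # the crossing line is x = 0.5, z = 0 within both triangles
        assert np.allclose(pts[:, 0], 0.5)
        assert np.allclose(pts[:, 2], 0.0)

    def test_disjoint_triangles_empty(self):
        t1 = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        t2 = t1 + [0, 0, 5]
        assert len(triangle_pair_intersection(t1, t2)) == 0

    def test_coplanar_overlapping_edge_points(self):
        t1 = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0], [0.0, 2.0, 0.0]])
        t2 = np.array([[1.0, -0.5, 0.0], [1.0, 1.5, 0.0], [3.0, 0.5, 0.0]])
        pts = triangle_pair_intersection(t1, t2)
        assert len(pts) >= 2


class TestDetectCollisions:
    def test_disjoint_meshes_empty(self):
        a = make_sphere(1.0, 2)
        b = translated(make_sphere(1.0, 2), [5, 0, 0])
        res = detect_collisions(a, b)
        assert not res
        assert res.points.shape == (0, 3)

    def test_obb_result_equals_brute_force(self):
        a = make_sphere(1.0, 3)  # 1280 faces
        b = translated(make_sphere(1.0, 2), [0.9, 0.1, 0.05])
        fast = detect_collisions(a, b)
        slow = detect_collisions_brute_force(a, b)
        assert fast.marked_a == slow.marked_a
        assert fast.marked_b == slow.marked_b
        fp = fast.points[np.lexsort(fast.points.T)]
        sp = slow.points[np.lexsort(slow.points.T)]
        assert np.allclose(fp, sp, atol=1e-9)

    def test_tube_through_slab_marked_sets_match_brute_force(self):
        slab = make_ridge(20.0, 0.0, 15)
        spec = TubeSpec(
            origin=(10, 10, -5), direction=(0, 0, 1),
            inner_radius_mm=1.5, outer_radius_mm=3.0, length_mm=10.0,
        )
        tube = make_tube(spec)
        fast = detect_collisions(slab, tube)
        slow = detect_collisions_brute_force(slab, tube)
        assert fast.marked_a == slow.marked_a
        assert fast.marked_b == slow.marked_b


class TestPolylines:
    def test_cylinder_plane_circle(self):
        slab = make_ridge(20.0, 0.0, 21)
        spec = TubeSpec(
            origin=(10, 10, -5), direction=(0, 0, 1),
            inner_radius_mm=2.0, outer_radius_mm=4.0, length_mm=10.0,
        )
        tube = make_tube(spec)
        res = detect_collisions(slab, tube)
        polylines = extract_intersection_polylines(res)
        closed = [pts for pts, c in polylines if c]
        assert len(closed) == 2  # bore circle and outer circle
        radii = sorted(
            float(np.linalg.norm(pts[:, :2] - [10, 10], axis=1).max()) for pts in closed
        )
        # each loop lies on its polygonal cylinder: r in [R cos(pi/32), R]
        assert radii[0] == pytest.approx(2.0, abs=1e-6)
        assert radii[1] == pytest.approx(4.0, abs=1e-6)
        for pts in closed:
            r = np.linalg.norm(pts[:, :2] - [10, 10], axis=1)
            R = r.max()
            assert r.min() >= R * np.cos(np.pi / 32) - 1e-6

    def test_single_pair_open_polyline(self):
        t1 = TriangleMesh(
            np.array([[0.0, -1.0, 0.0], [2.0, -1.0, 0.0], [0.0, 2.0, 0.0]]),
            np.array([[0, 1, 2]]),
        )
        t2 = TriangleMesh(
            np.array([[0.5, 0.0, -1.0], [0.5, 0.0, 1.0], [0.5, 2.0, 0.0]]),
            np.array([[0, 1, 2]]),
        )
        res = detect_collisions(t1, t2)
        polylines = extract_intersection_polylines(res)
        assert len(polylines) == 1
        pts, closed = polylines[0]
        assert not closed
        assert len(pts) == 2


class TestMergeUnion:
    def test_disjoint_raises_no_collision(self):
        a = make_sphere(1.0, 2)
        b = translated(make_sphere(1.0, 2), [5, 0, 0])
        with pytest.raises(MergeError, match="no collision"):
            merge_union(a, b)

    def test_overlapping_spheres_union_closed_with_volume_bounds(self):
        a = make_sphere(1.0, 3)
        b = translated(make_sphere(1.0, 3), [0.8, 0.05, 0.03])
        u = merge_union(a, b)
        assert check_closed(u)[0]
        va = orient_consistently(a).signed_volume()
        vu = orient_consistently(u).signed_volume()
        assert va <= vu <= 2 * va + 1e-9

    def test_union_symmetric(self):
        a = make_sphere(1.0, 2)
        b = translated(make_sphere(1.0, 2), [0.9, 0.02, 0.01])
        u1 = merge_union(a, b)
        u2 = merge_union(b, a)
        assert u1.n_faces == u2.n_faces
        p1 = np.asarray(sorted(map(tuple, np.round(u1.vertices, 9))))
        p2 = np.asarray(sorted(map(tuple, np.round(u2.vertices, 9))))
        assert np.allclose(p1, p2)

    def test_tube_through_template_shell_union_closed(self, ridge):
        from guideforge import fixtures as fx

        plan = fx.make_demo_plan(ridge, seed=7, n_tubes=0)
        shell, _ = design_template(ridge, plan)
        spec = TubeSpec(
            origin=(20.0, 20.0, 0.0), direction=(0.0, 0.0, 1.0),
            inner_radius_mm=1.25, outer_radius_mm=2.5, length_mm=14.0,
        )
        tube = make_tube(spec)
        u = merge_union(shell, tube)
        assert check_closed(u)[0]
        vol_shell = orient_consistently(shell).signed_volume()
        vol_union = orient_consistently(u).signed_volume()
        assert vol_union > vol_shell
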