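"""Mesh data model, I/O, and differential-geometry primitives."""

import math

import numpy as np
import pytest

from dentalseg.errors import (
    ClipError,
    EdgeLookupError,
    MeshFormatError,
    MeshValidationError,
    UndefinedDihedralError,
)
from dentalseg.fixtures import make_sphere
from dentalseg.mesh import (
    Plane,
    TriangleMesh,
    clip_below_plane,
    intersect_with_plane,
    load_mesh,
    principal_curvatures,
    trace_level_set,
)


# ----------------------------------------------------------------------
# I/O
class TestIO:
    def test_tetrahedron_roundtrip_counts(self, tetrahedron, tmp_path):
        """V-E+F = 2 for the closed tetrahedron, in all three formats."""
        for fmt in ("obj", "ply", "stl"):
            path = tmp_path / f"tet.{fmt}"
            tetrahedron.save(path)
            mesh = load_mesh(path)
            assert (mesh.n_vertices, mesh.n_edges, mesh.n_faces) == (4, 6, 4)
            assert mesh.euler_characteristic() == 2

    def test_vertex_order_preserved_for_obj(self, tetrahedron, tmp_path):
        path = tmp_path / "tet.obj"
        tetrahedron.save(path)
        mesh = load_mesh(path)
        np.testing.assert_allclose(mesh.vertices, tetrahedron.vertices, atol=1e-6)

    def test_repeated_index_face_rejected(self, tmp_path):
        path = tmp_path / "bad.obj"
        path.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1 2 2\n")
        with pytest.raises((MeshValidationError, MeshFormatError)):
            load_mesh(path)

    def test_unknown_format_rejected(self, tmp_path):
        path = tmp_path / "mesh.xyz"
        path.write_text("nonsense")
        with pytest.raises(MeshFormatError):
            load_mesh(path)

    def test_missing_file(self):
        with pytest.raises(MeshFormatError):
            load_mesh("/nonexistent/mesh.obj")


class TestValidation:
    def test_zero_area_face(self):
        with pytest.raises(MeshValidationError):
            TriangleMesh([[0, 0, 0], [1, 0, 0], [2, 0, 0]], [[0, 1, 2]])

    def test_nonmanifold_edge(self):
        v = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]]
        f = [[0, 1, 2], [0, 1, 3], [0, 1, 4]]  # edge (0,1) in three faces
        with pytest.raises(MeshValidationError):
            TriangleMesh(v, f)

    def test_one_ring_symmetry(self, sphere10):
        for i in (0, 100, 2000):
            for j in sphere10.one_ring(i):
                assert i in sphere10.one_ring(int(j))


# ----------------------------------------------------------------------
# discrete operators
class TestCotangentWeights:
    def test_equilateral_pair(self):
        """Interior edge between two equilateral triangles -> 1/sqrt(3)."""
        h = math.sqrt(3) / 2
        mesh = TriangleMesh(
            [[0, 0, 0], [1, 0, 0], [0.5, h, 0], [0.5, -h, 0]],
            [[0, 1, 2], [1, 0, 3]],
        )
        assert mesh.cotangent_weight((0, 1)) == pytest.approx(1 / math.sqrt(3), abs=1e-12)

    def test_square_diagonal_is_zero(self):
        mesh = TriangleMesh(
            [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], [[0, 1, 2], [0, 2, 3]]
        )
        assert mesh.cotangent_weight((0, 2)) == pytest.approx(0.0, abs=1e-12)

    def test_boundary_edge_single_angle(self):
        h = math.sqrt(3) / 2
        mesh = TriangleMesh([[0, 0, 0], [1, 0, 0], [0.5, h, 0]], [[0, 1, 2]])
        assert mesh.cotangent_weight((0, 1)) == pytest.approx(0.5 / math.sqrt(3), abs=1e-12)

    def test_missing_edge_raises(self, tetrahedron):
        with pytest.raises(EdgeLookupError):
            tetrahedron.cotangent_weight((0, 99))

    def test_row_sum_equals_diagonal(self, sphere10):
        """Sum of edge weights at vertex i equals the Laplacian diagonal."""
        from dentalseg.harmonic import build_laplacian

        w = sphere10.cotangent_weights()
        L = build_laplacian(sphere10, edge_weights=w)
        diag = L.diagonal()
        sums = np.zeros(sphere10.n_vertices)
        e = sphere10.edges
        np.add.at(sums, e[:, 0], w)
        np.add.at(sums, e[:, 1], w)
        np.testing.assert_allclose(sums, diag, atol=1e-10)


class TestDihedral:
    def test_coplanar_is_zero(self):
        mesh = TriangleMesh(
            [[0, 0, 0], [1, 0, 0], [0.5, 1, 0], [0.5, -1, 0]], [[0, 1, 2], [1, 0, 3]]
        )
        assert mesh.dihedral_angle((0, 1)) == pytest.approx(0.0, abs=1e-12)

    def test_tetrahedron_convex_positive(self, tetrahedron):
        """Angle between outward normals of a regular tetrahedron."""
        expected = math.pi - math.acos(1 / 3)
        assert tetrahedron.dihedral_angle((0, 1)) == pytest.approx(expected, abs=1e-12)

    def test_flipped_orientation_negates(self, tetrahedron):
        flipped = TriangleMesh(tetrahedron.vertices, tetrahedron.faces[:, ::-1])
        assert flipped.dihedral_angle((0, 1)) == pytest.approx(
            -tetrahedron.dihedral_angle((0, 1)), abs=1e-12
        )

    def test_boundary_edge_undefined(self):
        mesh = TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
        with pytest.raises(UndefinedDihedralError):
            mesh.dihedral_angle((0, 1))


class TestPrincipalCurvatures:
    def test_sphere(self, sphere10):
        cf = principal_curvatures(sphere10)
        assert np.median(cf.k_min) == pytest.approx(0.1, rel=0.10)
        assert np.median(cf.k_max) == pytest.approx(0.1, rel=0.10)
        assert (cf.k_min <= cf.k_max).all()

    def test_flat_grid_interior(self, grid):
        cf = principal_curvatures(grid)
        interior = ~np.isin(np.arange(grid.n_vertices), grid.boundary_vertices)
        assert np.abs(cf.k_min[interior]).max() < 1e-6
        assert np.abs(cf.k_max[interior]).max() < 1e-6

    def test_cylinder(self, cylinder):
        cf = principal_curvatures(cylinder)
        interior = ~np.isin(np.arange(cylinder.n_vertices), cylinder.boundary_vertices)
        assert np.median(cf.k_max[interior]) == pytest.approx(0.2, rel=0.10)
        assert abs(np.median(cf.k_min[interior])) < 0.02


# ----------------------------------------------------------------------
# plane intersection and clipping
class TestPlaneIntersection:
    def test_sphere_equator_single_closed_loop(self, sphere10):
        loops = intersect_with_plane(sphere10, Plane([0, 0, 0], [0, 0, 1]))
        assert len(loops) == 1
        assert loops[0].closed

    def test_two_disjoint_spheres_two_loops(self, sphere10):
        v = np.vstack([sphere10.vertices, sphere10.vertices + [30, 0, 0]])
        f = np.vstack([sphere10.faces, sphere10.faces + sphere10.n_vertices])
        two = TriangleMesh(v, f)
        loops = intersect_with_plane(two, Plane([0, 0, 0], [0, 0, 1]))
        assert len(loops) == 2
        assert all(lp.closed for lp in loops)

    def test_no_intersection_empty(self, sphere10):
        assert intersect_with_plane(sphere10, Plane([0, 0, 100], [0, 0, 1])) == []

    def test_loop_points_lie_on_plane(self, sphere10):
        plane = Plane([0, 0, 1.3], [0, 0, 1])
        (loop,) = intersect_with_plane(sphere10, plane)
        assert np.abs(plane.signed_distance(loop.points)).max() < 1e-12


class TestClip:
    def test_hemisphere_area(self, sphere10):
        """Clipped area of a radius-10 sphere at the equator ~ 2*pi*r^2."""
        clipped, omega3 = clip_below_plane(sphere10, Plane([0, 0, 0], [0, 0, 1]))
        clipped.validate()
        area = clipped.face_areas.sum()
        assert area == pytest.approx(2 * math.pi * 100, rel=0.02)
        assert len(omega3) > 0
        assert np.abs(clipped.vertices[omega3, 2]).max() < 1e-9

    def test_offset_plane_cut_vertices_on_plane(self, sphere10):
        plane = Plane([0, 0, 0.37], [0, 0, 1])
        clipped, omega3 = clip_below_plane(sphere10, plane)
        clipped.validate()
        assert np.abs(plane.signed_distance(clipped.vertices[omega3])).max() < 1e-9

    def test_no_intersection_raises(self, sphere10):
        with pytest.raises(ClipError):
            clip_below_plane(sphere10, Plane([0, 0, 100], [0, 0, 1]))


class TestTraceLevelSet:
    def test_interpolation_exactness(self, sphere10):
        z = sphere10.vertices[:, 2]
        for lp in trace_level_set(sphere10, z, 2.5):
            for (a, b), t in lp.edge_refs:
                assert abs((1 - t) * z[a] + t * z[b] - 2.5) < 1e-10

    def test_open_polyline_on_bounded_patch(self, grid):
        x = grid.vertices[:, 0]
        loops = trace_level_set(grid, x, 4.5)
        assert len(loops) == 1
        assert not loops[0].closed
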