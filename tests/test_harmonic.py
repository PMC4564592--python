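"""Concavity-aware weighting, Laplacian assembly, and the field solve."""

import math

import numpy as np
import pytest

from dentalseg.errors import ConstraintConflictError, SolverError
from dentalseg.harmonic import (
    EdgeWeightParams,
    build_constraints,
    build_laplacian,
    constraint_matrix,
    edge_concavity,
    gamma_factors,
    solve_field,
)
from dentalseg.mesh import TriangleMesh


def _folded_pair(angle):
    """Two equilateral triangles sharing edge (0,1), folded by ``angle``.

    angle = 0 is flat; positive folds the second triangle upward so the
    surface is concave across the shared edge (normals converge).
    """
    h = math.sqrt(3) / 2
    d = np.array([0.5, -h * math.cos(angle), h * math.sin(angle)])
    verts = np.array([[0, 0, 0], [1, 0, 0], [0.5, h, 0], d])
    return TriangleMesh(verts, [[0, 1, 2], [1, 0, 3]])


class TestSpecialWeights:
    def test_flat_edge_unattenuated(self):
        mesh = _folded_pair(0.0)
        from dentalseg.harmonic import special_edge_weight

        w = special_edge_weight(mesh, (0, 1), EdgeWeightParams())
        assert w == pytest.approx(1 / math.sqrt(3), abs=1e-12)

    def test_concave_fold_binary_attenuation(self):
        """30-degree concave fold with epsilon 0.05 -> 0.05x cot weight."""
        mesh = _folded_pair(math.radians(30))
        assert mesh.dihedral_angle((0, 1)) == pytest.approx(-math.radians(30), abs=1e-9)
        params = EdgeWeightParams(gamma_mode="binary", epsilon=0.05,
                                  concave_angle_tol=0.03)
        from dentalseg.harmonic import special_edge_weight

        w = special_edge_weight(mesh, (0, 1), params)
        assert w == pytest.approx(0.05 * mesh.cotangent_weight((0, 1)), rel=1e-12)

    def test_convex_never_attenuated(self, tetrahedron):
        gamma = gamma_factors(tetrahedron, EdgeWeightParams())
        np.testing.assert_array_equal(gamma, 1.0)

    def test_concavity_spreads_to_touching_edges(self):
        """Edges with a concave endpoint inherit the crease angle."""
        mesh = _folded_pair(math.radians(40))
        theta = edge_concavity(mesh)
        # every edge touches a vertex of the folded edge here
        assert (theta < -0.5).all()


class TestLaplacian:
    def test_row_sums_zero(self, two_bump):
        mesh, _ = two_bump
        L = build_laplacian(mesh, EdgeWeightParams())
        assert np.abs(np.asarray(L.sum(axis=1))).max() < 1e-10

    def test_symmetry_exact(self, two_bump):
        mesh, _ = two_bump
        L = build_laplacian(mesh, EdgeWeightParams())
        assert abs(L - L.T).max() == 0.0

    def test_matches_dense_assembly_on_grid(self, grid):
        """Independent dense cotangent-Laplacian assembly oracle."""
        L = build_laplacian(grid, edge_weights=grid.cotangent_weights())
        n = grid.n_vertices
        dense = np.zeros((n, n))
        v = grid.vertices
        for tri in grid.faces:
            for c in range(3):
                i, j, k = tri[c], tri[(c + 1) % 3], tri[(c + 2) % 3]
                # cotangent at corner i is opposite edge (j, k)
                u1 = v[j] - v[i]
                u2 = v[k] - v[i]
                cot = u1.dot(u2) / np.linalg.norm(np.cross(u1, u2))
                dense[j, k] -= cot / 2
                dense[k, j] -= cot / 2
                dense[j, j] += cot / 2
                dense[k, k] += cot / 2
        np.testing.assert_allclose(L.toarray(), dense, atol=1e-12)


class TestConstraints:
    def test_assignment_and_rhs(self):
        cons = build_constraints([3, 5], [7], [9], w=1000.0)
        assert dict(zip(cons.vertex_ids.tolist(), cons.types)) == {
            3: "p_max", 5: "p_max", 7: "p_min", 9: "p_mid"
        }
        rhs = dict(zip(cons.vertex_ids.tolist(), cons.rhs))
        assert rhs[3] == 1000.0 and rhs[7] == 0.0 and rhs[9] == 500.0

    def test_conflict_detection(self):
        with pytest.raises(ConstraintConflictError):
            build_constraints([1, 2], [2, 3], [], w=10.0)

    def test_constraint_matrix_shape(self):
        cons = build_constraints([0], [1], [2], w=50.0)
        C = constraint_matrix(cons, 5)
        assert C.shape == (3, 5)
        assert C.max() == 50.0


class TestSolveField:
    def test_cylinder_linear_field(self, cylinder):
        """Rings 0/1 at the cylinder ends reproduce phi = z/H exactly."""
        z = cylinder.vertices[:, 2]
        top = np.nonzero(np.abs(z - 20.0) < 1e-9)[0]
        bot = np.nonzero(np.abs(z) < 1e-9)[0]
        L = build_laplacian(cylinder, edge_weights=cylinder.cotangent_weights())
        f = solve_field(L, build_constraints(top, bot, [], w=1000.0))
        assert np.abs(f.phi - z / 20.0).max() < 1e-6

    def test_constant_field_reproduction(self, two_bump):
        mesh, _ = two_bump
        L = build_laplacian(mesh, EdgeWeightParams())
        mids = np.arange(0, mesh.n_vertices, 97)
        f = solve_field(L, build_constraints([], [], mids, w=1000.0))
        assert np.abs(f.phi - 0.5).max() < 1e-8

    def test_matches_dense_least_squares(self, random_mesh_factory):
        """Sparse solve equals a dense LS solve of the reduced stack."""
        rng = np.random.default_rng(3)
        mesh = random_mesh_factory(rng)
        L = build_laplacian(mesh, EdgeWeightParams())
        idx = rng.choice(mesh.n_vertices, 15, replace=False)
        cons = build_constraints(idx[:5], idx[5:10], idx[10:], w=1000.0)
        f = solve_field(L, cons)
        free = np.ones(mesh.n_vertices, dtype=bool)
        free[cons.vertex_ids] = False
        Lf = L.toarray()[free]
        # the reduced stack is square and consistent, so row scaling does
        # not move the solution; normalize rows so the dense solver sees
        # strongly attenuated rows too
        Lf /= np.linalg.norm(Lf, axis=1, keepdims=True)
        A = np.vstack([Lf, constraint_matrix(cons, mesh.n_vertices).toarray()])
        b = np.concatenate([np.zeros(int(free.sum())), cons.rhs])
        dense = np.linalg.lstsq(A, b, rcond=None)[0]
        assert np.abs(f.phi - dense).max() < 1e-8

    def test_range_bound_on_positive_weight_mesh(self, cylinder):
        """Soft-constraint maximum principle on a non-obtuse mesh."""
        rng = np.random.default_rng(7)
        z = cylinder.vertices[:, 2]
        L = build_laplacian(cylinder, edge_weights=cylinder.cotangent_weights())
        idx = rng.choice(cylinder.n_vertices, 20, replace=False)
        cons = build_constraints(idx[:7], idx[7:14], idx[14:], w=1000.0)
        f = solve_field(L, cons)
        assert f.phi.min() >= -0.01
        assert f.phi.max() <= 1.01

    def test_no_constraints_rejected(self, cylinder):
        L = build_laplacian(cylinder, edge_weights=cylinder.cotangent_weights())
        with pytest.raises(SolverError):
            solve_field(L, build_constraints([], [], [], w=1000.0))
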