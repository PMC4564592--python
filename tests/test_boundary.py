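"""Isoline extraction, loop scoring, boundary selection, face labeling."""

import numpy as np
import pytest

from dentalseg.boundary import (
    IsoLoop,
    annotate_enclosure,
    extract_isolines,
    interpolation_exactness,
    score_loop,
)
from dentalseg.errors import ScoringError
from dentalseg.harmonic import (
    EdgeWeightParams,
    build_constraints,
    build_laplacian,
    solve_field,
)
from dentalseg.mesh import principal_curvatures


@pytest.fixture(scope="module")
def cylinder_field(request):
    """Structured cylinder with the exact linear field phi = z/H."""
    from dentalseg.fixtures import make_cylinder

    cyl = make_cylinder(32, 11, 5.0, 20.0)
    z = cyl.vertices[:, 2]
    top = np.nonzero(np.abs(z - 20.0) < 1e-9)[0]
    bot = np.nonzero(np.abs(z) < 1e-9)[0]
    L = build_laplacian(cyl, edge_weights=cyl.cotangent_weights())
    f = solve_field(L, build_constraints(top, bot, [], w=1000.0))
    return cyl, f


@pytest.fixture(scope="module")
def dumbbell_field():
    """Two-bump dumbbell with pole constraints and the special weighting."""
    from dentalseg.fixtures import make_two_bump

    mesh, truth = make_two_bump()
    d_a = np.linalg.norm(mesh.vertices - truth.apex_a, axis=1)
    d_b = np.linalg.norm(mesh.vertices - truth.apex_b, axis=1)
    o1 = np.nonzero(d_a < 1.0)[0]
    o2 = np.nonzero(d_b < 1.0)[0]
    L = build_laplacian(mesh, EdgeWeightParams())
    f = solve_field(L, build_constraints(o1, o2, [], w=1000.0))
    return mesh, truth, f, o1, o2


class TestExtractIsolines:
    def test_cylinder_level_count_and_position(self, cylinder_field):
        """One closed ring at z = H/2 with one point per vertical column."""
        cyl, f = cylinder_field
        loops = extract_isolines(cyl, f, [0.5])
        assert len(loops) == 1
        lp = loops[0]
        assert lp.closed
        # crossings only on the 32 vertical edge columns and 32 diagonals
        assert np.abs(lp.points[:, 2] - 10.0).max() < 1e-6

    def test_level_outside_range_empty(self, cylinder_field):
        cyl, f = cylinder_field
        assert extract_isolines(cyl, f, [1.5]) == []

    def test_interpolation_exactness(self, cylinder_field):
        cyl, f = cylinder_field
        for lp in extract_isolines(cyl, f, [0.25, 0.5, 0.75]):
            assert interpolation_exactness(f, lp) < 1e-10

    def test_dumbbell_half_level_separates_constraints(self, dumbbell_field):
        mesh, truth, f, o1, o2 = dumbbell_field
        loops = [lp for lp in extract_isolines(mesh, f, [0.5]) if lp.closed]
        assert loops
        # 0.5-level separates the two constraint sets along the x axis
        x_loop = loops[0].points[:, 0].mean()
        assert mesh.vertices[o1, 0].max() < x_loop < mesh.vertices[o2, 0].min() or \
            mesh.vertices[o2, 0].max() < x_loop < mesh.vertices[o1, 0].min()


class TestScoring:
    def test_flat_region_scores_zero(self, cylinder_field):
        cyl, f = cylinder_field
        (lp,) = extract_isolines(cyl, f, [0.5])
        cf = principal_curvatures(cyl)
        assert score_loop(cyl, lp, cf) == pytest.approx(0.0, abs=1e-3)

    def test_crease_loop_beats_flank_loop(self, dumbbell_field):
        """The loop seated in the concave neck outscores off-crease loops."""
        mesh, truth, f, _, _ = dumbbell_field
        cf = principal_curvatures(mesh)
        loops = [lp for lp in extract_isolines(mesh, f, [0.3, 0.5, 0.7]) if lp.closed]
        scores = {}
        for lp in loops:
            d_crease = np.abs(lp.points[:, 0] - truth.crease_x).mean()
            scores[round(d_crease, 2)] = score_loop(mesh, lp, cf)
        in_crease = min(scores)  # distance of the crease-seated loop
        assert scores[in_crease] == max(scores.values())
        assert scores[in_crease] > 0.5

    def test_open_loop_rejected(self, grid):
        lp = IsoLoop(level=0.5, points=np.zeros((2, 3)), edge_refs=[], closed=False)
        cf = principal_curvatures(grid)
        with pytest.raises(ScoringError):
            score_loop(grid, lp, cf)


class TestSelectionAndLabels:
    def test_arch_boundaries_closed_and_counted(self, small_arch_segmented):
        mesh, truth, out = small_arch_segmented
        seg = out.segmentation
        assert len(seg.boundaries) == truth.n_teeth
        assert seg.flagged == []
        for lp in seg.boundaries.values():
            assert lp.closed
            assert len(lp.points) >= 3

    def test_labels_partition_faces(self, small_arch_segmented):
        mesh, truth, out = small_arch_segmented
        seg = out.segmentation
        assert len(seg.labels) == out.clipped_mesh.n_faces
        present = set(np.unique(seg.labels).tolist())
        assert present == set(range(truth.n_teeth + 1))

    def test_tooth_faces_edge_connected(self, small_arch_segmented):
        import scipy.sparse as sp
        from scipy.sparse.csgraph import connected_components

        mesh, truth, out = small_arch_segmented
        clipped = out.clipped_mesh
        labels = out.segmentation.labels
        ef = clipped.edge_faces
        inter = ef[:, 1] >= 0
        pairs = ef[inter]
        for tooth in range(1, truth.n_teeth + 1):
            faces = np.nonzero(labels == tooth)[0]
            sel = np.isin(pairs, faces).all(axis=1)
            sub = pairs[sel]
            remap = {f: i for i, f in enumerate(faces.tolist())}
            rows = [remap[a] for a in sub[:, 0]]
            cols = [remap[b] for b in sub[:, 1]]
            adj = sp.coo_matrix(
                (np.ones(len(rows)), (rows, cols)), shape=(len(faces), len(faces))
            )
            n_comp, _ = connected_components(adj, directed=False)
            assert n_comp == 1

    def test_level_monotonicity_single_cap(self, sphere10):
        """Moving the level away from the constraint grows the region.

        Single convex "tooth": a spherical cap with its apex constrained
        to 1 and the cut rim to 0.5; candidate regions for rising levels
        shrink monotonically toward the apex.
        """
        from dentalseg.features import FeaturePointGroups, FeaturePointSet
        from dentalseg.mesh import Plane, clip_below_plane

        cap, omega3 = clip_below_plane(sphere10, Plane([0, 0, 0], [0, 0, 1]))
        apex = np.nonzero(cap.vertices[:, 2] > 9.7)[0]
        L = build_laplacian(cap, edge_weights=cap.cotangent_weights())
        f = solve_field(L, build_constraints(apex, [], omega3, w=1000.0))
        group = FeaturePointGroups(
            groups=[FeaturePointSet(points=cap.vertices[apex], vertex_ids=apex)],
            arc_positions=[np.zeros(len(apex))],
        )
        levels = [0.55, 0.6, 0.65, 0.7, 0.75]
        loops = extract_isolines(cap, f, levels)
        annotate_enclosure(cap, f, loops, group)
        sizes = []
        for lv in levels:
            cands = [lp for lp in loops
                     if lp.level == lv and lp.enclosed_groups == frozenset({0})]
            assert len(cands) == 1
            sizes.append(int(cands[0].region_mask.sum()))
        assert sizes == sorted(sizes, reverse=True)
        assert sizes[0] > sizes[-1]

    def test_selected_levels_in_parity_bands(self, small_arch_segmented):
        """Parity-1 teeth select levels above 0.5; parity-0 below."""
        mesh, truth, out = small_arch_segmented
        for tooth_id, lp in out.segmentation.boundaries.items():
            parity = out.groups.parity(tooth_id - 1)
            if parity == 1:
                assert 0.5 < lp.level < 1.0
            else:
                assert 0.0 < lp.level < 0.5
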