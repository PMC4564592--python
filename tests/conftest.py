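"""Shared geometry fixtures.

Everything is generated programmatically and deterministically; the
expensive arch fixtures are session-scoped so the suite builds each one
once.
"""

import numpy as np
import pytest

from dentalseg.fixtures import (
    ArchFixtureSpec,
    make_arch,
    make_cylinder,
    make_grid,
    make_sphere,
    make_tetrahedron,
    make_two_bump,
)


@pytest.fixture(scope="session")
def tetrahedron():
    return make_tetrahedron()


@pytest.fixture(scope="session")
def sphere10():
    """Densely triangulated sphere of radius 10 mm."""
    return make_sphere(subdivisions=4, radius=10.0)


@pytest.fixture(scope="session")
def cylinder():
    """Structured open cylinder: 32 x 11 rings, r=5 mm, H=20 mm."""
    return make_cylinder(32, 11, 5.0, 20.0)


@pytest.fixture(scope="session")
def grid():
    return make_grid(10, 8, 1.0)


@pytest.fixture(scope="session")
def two_bump():
    """Asymmetric dumbbell with a concave neck groove + crease truth."""
    return make_two_bump()


@pytest.fixture(scope="session")
def small_arch():
    """6-tooth arch at moderate resolution, with ground truth."""
    spec = ArchFixtureSpec(n_teeth=6, mesh_resolution_mm=0.45, seed=11)
    return make_arch(spec)


@pytest.fixture(scope="session")
def small_arch_segmented(small_arch):
    """The small arch run end-to-end through the pipeline."""
    from dentalseg.pipeline import segment_mesh

    mesh, truth = small_arch
    out = segment_mesh(mesh, truth.all_feature_points(), truth.occlusal)
    return mesh, truth, out


@pytest.fixture()
def random_mesh_factory():
    """Factory for small random closed surfaces (perturbed icospheres)."""
    from dentalseg.mesh import TriangleMesh

    def make(rng):
        base = make_sphere(subdivisions=2, radius=3.0)  # 162 vertices
        verts = base.vertices * (1.0 + 0.15 * rng.standard_normal((base.n_vertices, 1)))
        verts = verts + 0.05 * rng.standard_normal(verts.shape)
        return TriangleMesh(verts, base.faces)

    return make
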