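"""Why the special concavity-aware weighting matters.

Two blended bumps of unequal size share a concave neck groove — a
miniature of the tooth-gum junction.  With the concavity-attenuated
weights the 0.5-isoline of the harmonic field locks onto the groove;
with plain cotangent weights it drifts millimetres away, because nothing
tells the field where the part boundary is.
"""

import numpy as np

from dentalseg.fixtures import make_two_bump
from dentalseg.harmonic import (
    EdgeWeightParams,
    build_constraints,
    build_laplacian,
    solve_field,
)
from dentalseg.mesh import trace_level_set

mesh, truth = make_two_bump()
print(f"dumbbell: {mesh.n_vertices} vertices, crease ring at x = {truth.crease_x:.2f} mm")

d_a = np.linalg.norm(mesh.vertices - truth.apex_a, axis=1)
d_b = np.linalg.norm(mesh.vertices - truth.apex_b, axis=1)
cons = build_constraints(np.nonzero(d_a < 1.0)[0], np.nonzero(d_b < 1.0)[0], [],
                         w=1000.0)

for label, L in (
    ("concavity-aware", build_laplacian(mesh, EdgeWeightParams())),
    ("plain cotangent ", build_laplacian(mesh, edge_weights=mesh.cotangent_weights())),
):
    field = solve_field(L, cons)
    loop = max(trace_level_set(mesh, field.phi, 0.5), key=lambda l: l.length)
    offset = np.abs(loop.points[:, 0] - truth.crease_x).mean()
    print(f"{label}: 0.5-isoline sits {offset:.3f} mm from the crease "
          f"(groove half-width {truth.crease_width} mm)")
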