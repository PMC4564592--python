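# Methods

This note documents the model and the numerical choices behind
`dentalseg`: what each stage computes, the parameters that matter, what
the synthetic fixtures do and do not emulate, and the design decisions
taken where the method left room.

## Discrete harmonic field

The field Φ assigns one scalar to each mesh vertex and satisfies the
discrete Laplace equation ΔΦ = 0 subject to Dirichlet data. The
Laplacian uses edge weights; with the plain cotangent scheme
`w_ij = (cot α_ij + cot β_ij)/2` (the two angles opposite edge ij,
boundary edges use the single available angle halved) the field is the
standard piecewise-linear harmonic interpolant: smooth, but blind to
shape. Obtuse triangles can make individual cotangent weights negative;
they are kept as-is, so the discrete maximum principle is only
guaranteed on non-obtuse meshes (and is asserted in tests only there).

### Concavity-aware weighting

Tooth boundaries live in concave grooves (the minima rule: part
boundaries follow concave discontinuities). The dental-targeted field
multiplies each cotangent weight by an attenuation factor γ_ij ∈ (0, 1]
that is small across concave creases, which concentrates the field's
variation — and therefore its isolines — inside the grooves.

A subtlety that matters: on a triangle mesh, a concave crease expresses
its dihedral angle on the edges running **along** it, while the edges
**crossing** it (the ones that conduct the field from one side to the
other) are locally flat. Attenuating edges by their own dihedral angle
therefore leaves the field across a crease almost unchanged — on a
structured surface-of-revolution test this is exact to 1e-9. `dentalseg`
instead assigns each edge an *effective concavity*: the most concave
signed dihedral found on the edge itself or on any edge incident to its
endpoints. Every edge touching a crease then carries the crease's
angle, and conduction across the groove is attenuated as intended.

The attenuation is, per edge with effective concavity θ (negative =
concave):

* `smooth` (default): γ = exp((θ + tol)/σ) for θ < −tol, else 1, with
  σ = 0.1 rad and dead zone tol = 0.10 rad. The dead zone sits above
  the dihedral noise floor of scanner-resolution meshes (measured
  ≈ ±0.09 rad on 0.3 mm fixtures), so ordinary surface roughness keeps
  full weight while genuine grooves (|θ| ≈ 0.5–2 rad) are attenuated by
  2–8 orders of magnitude, in proportion to how concave they are.
* `binary`: γ = ε (default 0.05) for θ < −tol, else 1. Kept selectable;
  it is markedly less accurate because the hard switch is ragged along
  sampled grooves.

Nonnegative attenuated weights below 1e-8 are lifted to 1e-8 so no edge
is ever exactly removed from the graph.

Sign conventions: the dihedral angle is the signed angle between
adjacent outward face normals, 0 for coplanar faces, positive convex;
principal curvatures are positive for a convex bump (sphere of radius r
has k = +1/r).

### Constraints and solve

Three vertex sets carry soft Dirichlet data: Ω₁ (odd tooth groups,
value 1), Ω₂ (even groups, value 0), Ω₃ (gingiva cut loop, value 0.5),
all with the same weight w = 1000 (constraint rows `c_ij = w`,
right-hand sides w, 0, 0.5 w). Feature points on the same tooth share a
value; neighboring teeth differ; the 0.5 contour anchors the field in
the gum so that every tooth boundary must separate its tooth's value
from 0.5.

The stacked system `A Φ = b`, `A = [L; C]`, is solved in the
least-squares sense with two implementation choices:

* **Laplacian rows of constrained vertices are dropped.** Their balance
  is dictated by the Dirichlet data, not by harmonicity; with the full
  stack, the least-squares compromise visibly bends the field near
  constrained boundary rings (0.07 error on the cylinder test instead
  of 1e-15). The reduced stack is square and consistent: a field
  harmonic at every free vertex that meets the constraints exactly is
  recovered exactly.
* **Row equilibration before the normal equations.** The normal
  equations `(LᵀL + CᵀC) Φ = Cᵀb'` are factorized with sparse LU (the
  SPD system that sparse Cholesky would factor; SciPy provides LU).
  Because strongly attenuated rows enter the normal equations squared
  (γ² ≈ 1e-14), they would otherwise vanish below machine precision and
  the crease physics would be silently lost. Scaling each Laplacian row
  to unit norm leaves the exact solution of the consistent system
  unchanged and keeps those rows numerically visible. Two iterative
  refinement passes against the (equilibrated) stacked system follow;
  the solution matches a dense least-squares solve to ~1e-10 on random
  meshes.

## Gingiva cutting

The sweep starts at the occlusal plane and moves toward the base in
steps of `sweep.step_mm` (default 1 mm). Per step, the plane-mesh
intersection is traced by marching triangles into closed loops; loops
with fewer than `sweep.min_loop_points` (default 8) points are treated
as tangential grazing and ignored. Steps with exactly one meaningful
loop are scored by the sample variance (1/(n−1) normalization) of the
minimum principal curvature sampled at the loop points (linearly
interpolated along the crossed edges). After the sweep completes, the
one-loop energies are min-max normalized to [0, 1] in one batch;
normalizing post hoc rather than incrementally makes the selection
independent of sweep direction bookkeeping. Scanning in sweep order,
the selected plane is the last step of the first maximal strictly
decreasing run of normalized energies below `sweep.energy_threshold`
(default 0.5); ties count as stopping. If the sweep exits the mesh
while still decreasing (or never drops below the threshold), the last
one-loop plane is used.

Clipping splits crossing triangles exactly at the plane and keeps the
occlusal side; the newly created cut vertices lie on the plane to
within 1e-9 mm and are recorded as Ω₃ (original vertices already on the
plane are included — they lie on the cut loop too). The clipped mesh is
revalidated (manifold, nondegenerate).

## Curvature estimation

Per-vertex principal curvatures come from a least-squares quadric
`h = q₀x² + q₁xy + q₂y² + q₃x + q₄y` fit over the 2-ring neighborhood
in the vertex tangent frame (height measured along the area-weighted
vertex normal), followed by the shape operator of the graph. The 2-ring
gives robustness to sampling noise at the cost of slightly smoothing
narrow grooves; vertices with fewer than five neighbors get curvature 0
with a warning. The estimator reproduces sphere/plane/cylinder closed
forms within 10 % at fixture resolutions.

## Boundary extraction

`boundary.n_levels` (default 50) isoline levels are sampled uniformly
inside each parity band (0, 0.5) and (0.5, 1) — a tooth constrained to
1 must be separated from the 0.5 gum contour by a level above 0.5, and
symmetrically for 0-teeth. Isoloops are traced with exact linear
interpolation along edges (verified to 1e-10). A closed loop's enclosed
region is the level-set side that does not reach the mesh boundary;
when several loops at one level bound the same region (spurious holes
from field overshoot near strongly attenuated edges), only the longest
— the region's outer contour — represents it. Candidates for tooth g
must enclose all of g's feature vertices and no other group's.

The voting score is the mean positive concavity along the loop,
`(1/len) ∮ max(0, −k_min) ds`: loops seated in the groove bottom score
highest. Ties break toward the level farther from the tooth's
constraint value (the larger enclosed region). Faces with a vertex
inside a tooth's region get that tooth's label (boundary-crossed faces
fall to the tooth side — downstream orthodontic use prefers gum-side
slack); conflicts go to the tooth holding more of the face's vertices;
everything else is non-teeth (label 0). Boundaries must be pairwise
non-crossing in the region sense (disjoint or nested); loops of
adjacent teeth may legitimately cross the same mesh edge at different
parameters where the field traverses an interstice within one edge.

No smoothing or snake refinement is applied afterwards — the point of
the harmonic isoloop construction is that none is needed.

## Synthetic fixtures

The arch generator emulates the input population: ellipsoidal teeth
placed along a parabolic arch and blended into a swept gum tube by a
smooth (exponential) implicit union, extracted by marching cubes.
Defaults: 14 teeth, tooth radius 4 mm (mesiodistal semi-axis 0.92 r so
uncrowded neighbors keep a resolvable interstice), crown height 7 mm,
gum radius 6 mm, mesh resolution 0.3 mm (intraoral-scanner scale),
seeded ±4 % size jitter. A concave trench of depth 1.5 mm and width
0.8 mm — sulcus-scale — is carved along every tooth-gum and tooth-tooth
junction at the locus where the two nearest component SDFs are equal;
the trench gap is normalized by its spatial gradient on the sampling
grid so the stated width is a true spatial width even between strongly
overlapping (crowded) teeth. Ground truth comes from the same implicit
model: per-face labels by nearest component at the centroid, per-tooth
boundary curves as the zero level set of the component-dominance
function on the mesh, cusp-like feature points (apex plus four crown
points at 95 % height, mimicking a cusp detector's output), and the
occlusal plane just below all feature points. Crowding shrinks the
spacing so teeth overlap; missing teeth leave a gap and the remaining
teeth are renumbered.

What the fixtures do **not** emulate: scanner noise and holes (optional
Gaussian vertex jitter exists but defaults to 0), enamel texture,
realistic cusp anatomy, and dentist-drawn ground truth — the reference
boundary is the generative model's junction locus, not a human
annotation. Passing the end-to-end tests therefore shows the pipeline
recovers the boundaries of this model family at scanner-like sampling;
it does not certify clinical accuracy.

The two-bump crease fixture is a structured surface of revolution (two
unequal blended spheres with a Gaussian neck groove, ring-lattice
meshed) rather than a marching-cubes extraction: voxel meshes leave
flat leak paths through any crease, which would confound the pure
shape-awareness property the fixture exists to demonstrate. Its crease
ring position is known in closed form and cross-checked by a numeric
scan of the profile's maximal concavity.

## Evaluation metrics

Boundary accuracy is the mean symmetric closest-point distance between
polylines, both resampled at 0.05 mm (the mean of the two directional
means); the generative junction curve is the reference. Label agreement
is the unweighted fraction of clipped-mesh faces whose label matches
the analytic label at the face centroid, after matching result teeth to
ground-truth teeth through their feature points. Unsegmented teeth are
reported as excluded rather than silently dropped.

## Problem sizes and defaults used in the shipped checks

The test-suite and the acceptance script run the pipeline on 14-tooth
arches at 0.3 mm resolution (~200 k faces, a few seconds per jaw on one
CPU core) and the gingiva-cut population on 8-tooth arches at 0.45 mm;
solver oracles use random ≤ 500-vertex meshes where dense least-squares
comparison is exact. Typical measured results: mean boundary error
0.06–0.07 mm with label agreement ≈ 0.99 across plain, crowded (0.2)
and partially edentulous arches; cut-plane success 8/8; sparse-vs-dense
solver agreement ~1e-10; cylinder and constant fields exact to 1e-15.

## Known limitations

* The γ attenuation is this package's own operationalization of
  concavity-aware weighting; published variants differ in detail and
  can be slotted in through `EdgeWeightParams`.
* Feature points and the occlusal plane are inputs; automatic cusp
  detection is out of scope (the fixtures provide them analytically).
* Very obtuse, poor-quality triangulations weaken both the cotangent
  weights and the dihedral-based concavity signal; the pipeline expects
  scanner-grade meshes (it validates manifoldness and nondegeneracy up
  front).
* Teeth without any feature point cannot be segmented (they are part of
  the "non-teeth" region by construction).
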