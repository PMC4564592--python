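"""Deterministic generators for all test geometry.

The centerpiece is a parametric dental arch: smooth ellipsoidal "teeth"
blended into a swept gum tube by a smooth implicit union, with a concave
trench carved along every tooth-gum and tooth-tooth junction.  Because
the geometry is implicit, the ground truth (per-face labels, boundary
curves, cusp apices, occlusal plane) is known analytically and is emitted
alongside the mesh.  Analytic solids (sphere, cylinder, grid, two-bump
crease shape) back the closed-form oracles used in the test-suite.

All generators are deterministic functions of their spec (seeded jitter
only), so the same spec reproduces the identical mesh.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import trimesh as _tm
from scipy.interpolate import interp1d
from scipy.spatial import cKDTree
from scipy.special import logsumexp
from skimage.measure import marching_cubes

from .errors import FixtureSpecError
from .mesh import Plane, TriangleMesh, trace_level_set

# ----------------------------------------------------------------------
# implicit components


class _Ellipsoid:
    """Approximate SDF of an ellipsoid, optionally rotated about z."""

    def __init__(self, center, axes, theta: float = 0.0):
        self.center = np.asarray(center, dtype=float)
        self.axes = np.asarray(axes, dtype=float)
        self.theta = float(theta)
        c, s = np.cos(-self.theta), np.sin(-self.theta)
        self._rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

    def sdf(self, pts: np.ndarray) -> np.ndarray:
        p = (pts - self.center) @ self._rot.T
        r = np.linalg.norm(p / self.axes, axis=1)
        return (r - 1.0) * self.axes.min()

    @property
    def top(self) -> np.ndarray:
        return self.center + np.array([0.0, 0.0, self.axes[2]])

    def cusp_ring(self, height_frac: float = 0.95) -> np.ndarray:
        """Four cusp-like surface points around the crown near the top.

        Mimics the anatomical feature points (cusps / incisal-edge ends)
        a detector would supply: mesial/distal and buccal/lingual points
        at ``height_frac`` of the vertical semi-axis.
        """
        s = float(np.sqrt(max(1.0 - height_frac**2, 0.0)))
        local = np.array(
            [
                [+s * self.axes[0], 0.0, height_frac * self.axes[2]],
                [-s * self.axes[0], 0.0, height_frac * self.axes[2]],
                [0.0, +s * self.axes[1], height_frac * self.axes[2]],
                [0.0, -s * self.axes[1], height_frac * self.axes[2]],
            ]
        )
        return local @ self._rot + self.center


class _Tube:
    """SDF of a tube (capsule) around a densely sampled polyline."""

    def __init__(self, samples: np.ndarray, radius: float):
        self.samples = np.asarray(samples, dtype=float)
        self.radius = float(radius)
        self._tree = cKDTree(self.samples)

    def sdf(self, pts: np.ndarray) -> np.ndarray:
        d, _ = self._tree.query(pts, k=1)
        return d - self.radius


class _HalfSpace:
    """SDF of the half space below a horizontal plane z = z0."""

    def __init__(self, z0: float):
        self.z0 = float(z0)

    def sdf(self, pts: np.ndarray) -> np.ndarray:
        return pts[:, 2] - self.z0


def _smooth_min(values: np.ndarray, k: float) -> np.ndarray:
    """Exponential smooth minimum over axis 0 (blend radius ``k`` mm)."""
    return -k * logsumexp(-values / k, axis=0)


def _smin_and_delta(components: Sequence, pts: np.ndarray, blend: float):
    """Smooth union value and gap Δ between the two nearest components."""
    vals = np.stack([c.sdf(pts) for c in components], axis=0)
    smin = _smooth_min(vals, blend)
    if vals.shape[0] < 2:
        delta = np.full(len(pts), np.inf)
    else:
        part = np.partition(vals, 1, axis=0)
        delta = part[1] - part[0]
    return smin, delta


def _eval_field(
    components: Sequence, pts: np.ndarray, blend: float, depth: float, width: float
) -> np.ndarray:
    """Pointwise field (trench without gradient normalization; used only
    for orientation probes where the exact trench profile is irrelevant)."""
    smin, delta = _smin_and_delta(components, pts, blend)
    if depth > 0 and np.isfinite(delta).any():
        smin = smin + depth * np.exp(-((delta / width) ** 2))
    return smin


def _mesh_from_implicit(
    components: Sequence,
    bounds_lo: np.ndarray,
    bounds_hi: np.ndarray,
    resolution: float,
    blend: float,
    depth: float,
    width: float,
) -> TriangleMesh:
    """Extract the zero level set on a regular grid via marching cubes.

    The concave trench along inter-component junctions is carved with its
    width measured in space: the junction gap Δ is normalized by |∇Δ|
    (grid finite differences), so narrow interstices between strongly
    overlapping teeth still receive a resolvable groove.
    """
    lo = np.asarray(bounds_lo, dtype=float)
    hi = np.asarray(bounds_hi, dtype=float)
    shape = np.maximum(np.ceil((hi - lo) / resolution).astype(int) + 1, 2)
    axes = [lo[i] + resolution * np.arange(shape[i]) for i in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    vol = np.empty(len(pts))
    delta = np.empty(len(pts))
    chunk = 400_000
    for s0 in range(0, len(pts), chunk):
        sl = slice(s0, s0 + chunk)
        vol[sl], delta[sl] = _smin_and_delta(components, pts[sl], blend)
    vol = vol.reshape(shape)
    if depth > 0 and np.isfinite(delta).any():
        delta = delta.reshape(shape)
        grads = np.gradient(delta, resolution, edge_order=1)
        gnorm = np.sqrt(grads[0] ** 2 + grads[1] ** 2 + grads[2] ** 2)
        gnorm = np.clip(gnorm, 0.5, None)
        vol = vol + depth * np.exp(-((delta / (width * gnorm)) ** 2))
    # avoid near-zero samples: crossings at grid vertices make degenerate
    # triangles; a 1e-4 mm offset is far below any geometric tolerance here
    tiny = 1e-4
    vol = np.where(np.abs(vol) < tiny, tiny, vol)
    verts, faces, _, _ = marching_cubes(
        vol, level=0.0, spacing=(resolution, resolution, resolution)
    )
    verts = verts + lo
    mesh = _tm.Trimesh(verts, faces, process=False)
    # orient outward: interior has negative field values
    tm2 = _tm.Trimesh(verts, faces, process=True)
    if tm2.is_watertight and tm2.volume < 0:
        faces = faces[:, ::-1]
    else:
        # probe: push a vertex along its normal, field must increase
        m = _tm.Trimesh(verts, faces, process=False)
        vn = m.vertex_normals
        probe = verts[:64] + 0.5 * resolution * vn[:64]
        f_out = _eval_field(components, probe, blend, depth, width)
        f_at = _eval_field(components, verts[:64], blend, depth, width)
        if np.median(f_out - f_at) < 0:
            faces = faces[:, ::-1]
    out = TriangleMesh(verts, faces, validate=False)
    out.validate()
    return out


# ----------------------------------------------------------------------
# analytic solids


def make_cylinder(n_theta: int, n_z: int, radius: float, height: float) -> TriangleMesh:
    """Open cylinder with a translationally uniform triangulation.

    ``n_theta * n_z`` vertices; every quad split the same way, so a field
    linear in z is exactly discrete-harmonic at interior vertices.
    """
    if n_theta < 3 or n_z < 2:
        raise FixtureSpecError("cylinder needs n_theta >= 3 and n_z >= 2")
    if radius <= 0 or height <= 0:
        raise FixtureSpecError("cylinder radius and height must be positive")
    theta = 2.0 * np.pi * np.arange(n_theta) / n_theta
    z = np.linspace(0.0, height, n_z)
    tt, zz = np.meshgrid(theta, z, indexing="ij")  # (n_theta, n_z)
    verts = np.stack(
        [radius * np.cos(tt).ravel(), radius * np.sin(tt).ravel(), zz.ravel()], axis=1
    )

    def vid(it, iz):
        return (it % n_theta) * n_z + iz

    faces = []
    for it in range(n_theta):
        for iz in range(n_z - 1):
            a = vid(it, iz)
            b = vid(it + 1, iz)
            c = vid(it + 1, iz + 1)
            d = vid(it, iz + 1)
            faces.append((a, b, c))
            faces.append((a, c, d))
    return TriangleMesh(verts, np.asarray(faces))


def make_sphere(subdivisions: int = 3, radius: float = 1.0) -> TriangleMesh:
    """Icosphere (10*4^n + 2 vertices), outward oriented."""
    ico = _tm.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(ico.vertices), np.asarray(ico.faces))


def make_grid(m: int, n: int, spacing: float = 1.0) -> TriangleMesh:
    """Flat rectangular grid in the z=0 plane, 2(m-1)(n-1) faces."""
    if m < 2 or n < 2:
        raise FixtureSpecError("grid needs m, n >= 2")
    xs = spacing * np.arange(m)
    ys = spacing * np.arange(n)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    verts = np.stack([xx.ravel(), yy.ravel(), np.zeros(m * n)], axis=1)

    def vid(i, j):
        return i * n + j

    faces = []
    for i in range(m - 1):
        for j in range(n - 1):
            a, b, c, d = vid(i, j), vid(i + 1, j), vid(i + 1, j + 1), vid(i, j + 1)
            faces.append((a, b, c))
            faces.append((a, c, d))
    return TriangleMesh(verts, np.asarray(faces))


def make_tetrahedron(scale: float = 1.0) -> TriangleMesh:
    """Regular tetrahedron with outward-oriented faces."""
    v = scale * np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    )
    f = np.array([[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
    return TriangleMesh(v, f)


# ----------------------------------------------------------------------
# two-bump crease fixture


@dataclass
class TwoBumpTruth:
    """Ground truth for the crease between two blended bumps."""

    crease_x: float  # x position of the concave crease line
    crease_width: float  # half band width (mm)
    apex_a: np.ndarray  # top of the larger bump
    apex_b: np.ndarray  # top of the smaller bump
    apex_a_vid: int
    apex_b_vid: int


def make_two_bump(
    groove_depth: float = 0.8,
    groove_width: float = 0.8,
    separation: float = 6.5,
    radius_a: float = 6.0,
    radius_b: float = 3.5,
    n_segments: int = 96,
    ds: float = 0.25,
) -> tuple[TriangleMesh, TwoBumpTruth]:
    """Closed dumbbell of revolution: two unequal spheres with a concave
    neck groove, meshed as a structured ring lattice.

    The profile follows the two circle arcs from pole to pole; a Gaussian
    dip of ``groove_depth`` and half-width ``groove_width`` is carved
    into the radius around the circle-intersection ring, so the crease
    location is known exactly (``crease_x``) and every edge crossing the
    groove carries the true concave dihedral angle (a structured mesh,
    unlike a voxel extraction, has no flat leak paths through a crease).

    The asymmetry (radius_a != radius_b) matters: a harmonic field with
    plain cotangent weights between the two pole constraints places its
    0.5-isoline away from the crease, while the concavity-attenuated
    field locks onto it.
    """
    if separation >= radius_a + radius_b:
        raise FixtureSpecError("bumps must overlap to form a neck crease")
    xa = -separation / 2.0
    xb = +separation / 2.0
    crease_x = (radius_a**2 - radius_b**2) / (2.0 * (xb - xa)) + 0.5 * (xa + xb)
    r_neck = np.sqrt(radius_a**2 - (crease_x - xa) ** 2)
    if groove_depth >= r_neck:
        raise FixtureSpecError("groove depth would pinch the neck off")

    # profile arcs, parametrized by polar angle on each sphere
    phi_a_end = np.arccos((crease_x - xa) / radius_a)  # angle at crossing
    phi_b_end = np.arccos((crease_x - xb) / radius_b)
    n_a = max(int(np.ceil(radius_a * (np.pi - phi_a_end) / ds)), 8)
    n_b = max(int(np.ceil(radius_b * phi_b_end / ds)), 8)
    # from pole A (phi=pi) down to the crossing (phi=phi_a_end)
    phis_a = np.linspace(np.pi, phi_a_end, n_a + 1)
    prof_a = np.stack([xa + radius_a * np.cos(phis_a), radius_a * np.sin(phis_a)], 1)
    phis_b = np.linspace(phi_b_end, 0.0, n_b + 1)
    prof_b = np.stack([xb + radius_b * np.cos(phis_b), radius_b * np.sin(phis_b)], 1)
    profile = np.vstack([prof_a, prof_b[1:]])  # crossing point shared
    # arc length from the crease ring, for the Gaussian dip
    seg = np.linalg.norm(np.diff(profile, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    s_crease = s[n_a]
    dip = groove_depth * np.exp(-(((s - s_crease) / groove_width) ** 2))
    # fade the dip near the poles so r stays positive
    dip *= np.clip(profile[:, 1] / (2.0 * groove_depth), 0.0, 1.0)
    radii = profile[:, 1] - dip
    xs = profile[:, 0]

    # structured ring lattice with pole fans
    interior = slice(1, len(profile) - 1)
    ring_x = xs[interior]
    ring_r = radii[interior]
    n_rings = len(ring_x)
    theta = 2.0 * np.pi * np.arange(n_segments) / n_segments
    verts = [np.array([xs[0], 0.0, 0.0])]
    for rx, rr in zip(ring_x, ring_r):
        verts.append(
            np.stack([np.full(n_segments, rx), rr * np.cos(theta), rr * np.sin(theta)], 1)
        )
    verts.append(np.array([xs[-1], 0.0, 0.0]))
    vertices = np.vstack([v.reshape(-1, 3) for v in verts])
    pole_a = 0
    pole_b = len(vertices) - 1

    def rv(ring, k):
        return 1 + ring * n_segments + (k % n_segments)

    faces = []
    for k in range(n_segments):
        faces.append((pole_a, rv(0, k + 1), rv(0, k)))
    for ring in range(n_rings - 1):
        for k in range(n_segments):
            a = rv(ring, k)
            b = rv(ring, k + 1)
            c = rv(ring + 1, k + 1)
            d = rv(ring + 1, k)
            faces.append((a, b, c))
            faces.append((a, c, d))
    for k in range(n_segments):
        faces.append((pole_b, rv(n_rings - 1, k), rv(n_rings - 1, k + 1)))
    mesh = TriangleMesh(vertices, np.asarray(faces))
    # orient outward (positive enclosed volume)
    v0 = mesh.vertices[mesh.faces[:, 0]]
    vol = np.einsum(
        "ij,ij->i",
        v0,
        np.cross(mesh.vertices[mesh.faces[:, 1]], mesh.vertices[mesh.faces[:, 2]]),
    ).sum() / 6.0
    if vol < 0:
        mesh = TriangleMesh(vertices, np.asarray(faces)[:, ::-1])

    truth = TwoBumpTruth(
        crease_x=float(crease_x),
        crease_width=groove_width,
        apex_a=mesh.vertices[pole_a].copy(),
        apex_b=mesh.vertices[pole_b].copy(),
        apex_a_vid=int(pole_a),
        apex_b_vid=int(pole_b),
    )
    return mesh, truth


# ----------------------------------------------------------------------
# dental arch fixture


@dataclass
class ArchFixtureSpec:
    """Parameters of the synthetic dental arch.

    Dimensions are mm.  ``crowding`` shrinks the spacing of adjacent
    teeth so they overlap by that fraction of a tooth diameter;
    ``missing_teeth`` removes teeth from their arch positions leaving a
    gap, as in partially edentulous jaws.
    """

    n_teeth: int = 14
    tooth_radius_mm: float = 4.0
    tooth_height_mm: float = 7.0
    groove_depth_mm: float = 1.5
    groove_width_mm: float = 0.8
    crowding: float = 0.0
    missing_teeth: tuple = ()
    gum_height_mm: float = 6.0
    mesh_resolution_mm: float = 0.3
    jitter: float = 0.04
    noise_mm: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_teeth < 1:
            raise FixtureSpecError("need at least one tooth")
        for name in ("tooth_radius_mm", "tooth_height_mm", "gum_height_mm",
                     "mesh_resolution_mm", "groove_width_mm"):
            if getattr(self, name) <= 0:
                raise FixtureSpecError(f"{name} must be positive")
        if not 0.0 <= self.crowding < 0.5:
            raise FixtureSpecError("crowding must lie in [0, 0.5)")
        if self.mesh_resolution_mm > self.groove_width_mm:
            raise FixtureSpecError(
                "mesh resolution coarser than the groove width cannot resolve grooves"
            )
        if any(i < 0 or i >= self.n_teeth for i in self.missing_teeth):
            raise FixtureSpecError("missing_teeth indices out of range")


@dataclass
class ArchGroundTruth:
    """Analytic ground truth accompanying a generated arch mesh.

    ``labels`` are per-face: 0 = gum/base, 1..K = teeth ordered along
    the arch (missing teeth renumbered away).  ``label_points`` can
    relabel arbitrary surface points (e.g. faces of a clipped mesh).
    """

    labels: np.ndarray
    boundaries: dict
    apices: dict
    apex_vertex_ids: dict
    feature_points: dict  # tooth id -> (k, 3) cusp-like feature points
    occlusal: Plane
    tooth_bottom_z: dict
    base_z: float
    _components: list = field(default_factory=list, repr=False)

    def all_feature_points(self) -> np.ndarray:
        """Stacked feature points of all teeth, arch order."""
        return np.vstack([self.feature_points[t] for t in sorted(self.feature_points)])

    @property
    def n_teeth(self) -> int:
        return len(self.apices)

    def label_points(self, pts: np.ndarray) -> np.ndarray:
        """Analytic label of surface points: nearest implicit component."""
        pts = np.asarray(pts, dtype=float).reshape(-1, 3)
        vals = np.stack([c.sdf(pts) for c in self._components], axis=0)
        # component 0 is the gum tube -> label 0; teeth follow in order
        return np.argmin(vals, axis=0)


def _arch_curve(c2: float, arc_length: float):
    """Half-width X with parabola y=c2 x^2 arc length = ``arc_length``.

    Returns dense samples (x, y) and cumulative arc length for mapping
    arc positions to plane coordinates.
    """
    def arc_of(xmax):
        xs = np.linspace(-xmax, xmax, 4001)
        ys = c2 * xs**2
        return np.sum(np.hypot(np.diff(xs), np.diff(ys))), xs, ys

    lo_x, hi_x = arc_length / 4.0, arc_length
    for _ in range(60):
        mid = 0.5 * (lo_x + hi_x)
        total, _, _ = arc_of(mid)
        if total < arc_length:
            lo_x = mid
        else:
            hi_x = mid
    xmax = 0.5 * (lo_x + hi_x)
    total, xs, ys = arc_of(xmax)
    s = np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(xs), np.diff(ys)))])
    return xs, ys, s


def make_arch(spec: ArchFixtureSpec) -> tuple[TriangleMesh, ArchGroundTruth]:
    """Generate a dental-arch mesh and its analytic ground truth."""
    rng = np.random.default_rng(spec.seed)
    r_t = spec.tooth_radius_mm
    spacing = 2.0 * r_t * (1.0 - spec.crowding)
    arc_total = spacing * (spec.n_teeth - 1) + 2.0 * r_t + 2.0
    c2 = 0.025
    xs, ys, s = _arch_curve(c2, arc_total)
    s_mid = s[-1] / 2.0
    x_of_s = interp1d(s, xs)
    y_of_s = interp1d(s, ys)

    # gum tube polyline at z = 0, finely sampled to keep the SDF smooth
    gum_s = np.arange(0.0, s[-1], 0.1)
    gum_line = np.stack(
        [x_of_s(gum_s), y_of_s(gum_s), np.zeros_like(gum_s)], axis=1
    )
    r_g = spec.gum_height_mm
    gum = _Tube(gum_line, r_g)

    components: list = [gum]
    apex_analytic: dict[int, np.ndarray] = {}
    present = [i for i in range(spec.n_teeth) if i not in set(spec.missing_teeth)]
    c_t = spec.tooth_height_mm + 1.0  # buried 1 mm below the gum top
    for rank, i in enumerate(present, start=1):
        pos_s = s_mid + (i - (spec.n_teeth - 1) / 2.0) * spacing
        x = float(x_of_s(pos_s))
        y = float(y_of_s(pos_s))
        tangent = np.arctan2(2.0 * c2 * x, 1.0)
        jit = 1.0 + spec.jitter * rng.uniform(-1.0, 1.0, size=3)
        # mesiodistal semi-axis slightly under half the spacing so that
        # uncrowded neighbors leave a resolvable interstice
        axes = np.array([0.92 * r_t * jit[0], 0.9 * r_t * jit[1], c_t * jit[2]])
        center = np.array([x, y, r_g - 1.0 + 0.2 * rng.uniform(-1.0, 1.0) * spec.jitter * 10])
        tooth = _Ellipsoid(center, axes, theta=tangent)
        components.append(tooth)
        apex_analytic[rank] = tooth.top

    pad = 3.0
    lo = np.array([xs.min() - r_g - pad, ys.min() - r_g - pad, -r_g - pad])
    z_top = max(p[2] for p in apex_analytic.values())
    hi = np.array([xs.max() + r_g + pad, ys.max() + r_g + pad, z_top + pad])
    mesh = _mesh_from_implicit(
        components, lo, hi, spec.mesh_resolution_mm,
        blend=0.7, depth=spec.groove_depth_mm, width=spec.groove_width_mm,
    )

    if spec.noise_mm > 0:
        disp = rng.normal(0.0, spec.noise_mm, size=mesh.n_vertices)
        mesh = TriangleMesh(
            mesh.vertices + disp[:, None] * mesh.vertex_normals, mesh.faces,
            validate=False,
        )
        mesh.validate()

    # ground truth -----------------------------------------------------
    centroids = mesh.vertices[mesh.faces].mean(axis=1)
    labels = _argmin_labels(components, centroids)

    vertex_vals = np.stack([c.sdf(mesh.vertices) for c in components], axis=0)
    boundaries: dict[int, np.ndarray] = {}
    for rank in apex_analytic:
        others = np.delete(vertex_vals, rank, axis=0).min(axis=0)
        g = vertex_vals[rank] - others
        loops = trace_level_set(mesh, g, 0.0)
        closed = [lp for lp in loops if lp.closed]
        if not closed:
            closed = loops
        best = max(closed, key=lambda lp: lp.length)
        boundaries[rank] = best.points.copy()

    tree = cKDTree(mesh.vertices)
    apices: dict[int, np.ndarray] = {}
    apex_vids: dict[int, int] = {}
    feature_points: dict[int, np.ndarray] = {}
    for rank, top in apex_analytic.items():
        _, vid = tree.query(top)
        apices[rank] = mesh.vertices[vid].copy()
        apex_vids[rank] = int(vid)
        tooth = components[rank]
        raw = np.vstack([tooth.top[None], tooth.cusp_ring()])
        _, vids = tree.query(raw)
        feature_points[rank] = mesh.vertices[np.unique(vids)].copy()

    tooth_bottom_z = {
        rank: float(centroids[labels == rank, 2].min()) for rank in apex_analytic
    }
    # occlusal plane just below every feature point so it is unambiguously
    # on the occlusal side of the prior-knowledge inputs
    z_plane = min(float(fp[:, 2].min()) for fp in feature_points.values()) - 0.1
    occlusal = Plane(np.array([0.0, float(y_of_s(s_mid)), z_plane]), np.array([0.0, 0.0, 1.0]))

    truth = ArchGroundTruth(
        labels=labels,
        boundaries=boundaries,
        apices=apices,
        apex_vertex_ids=apex_vids,
        feature_points=feature_points,
        occlusal=occlusal,
        tooth_bottom_z=tooth_bottom_z,
        base_z=-r_g,
        _components=components,
    )
    return mesh, truth


def _argmin_labels(components, pts):
    vals = np.stack([c.sdf(pts) for c in components], axis=0)
    return np.argmin(vals, axis=0)
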