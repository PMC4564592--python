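"""Tooth anatomical feature points, the occlusal plane, and per-tooth grouping.

Feature points (cusps of canines/premolars/molars, incisal-edge endpoints
of incisors) and the occlusal plane are inputs to the pipeline, supplied
as a plain-text sidecar file.  A degree-4 dental-arch curve is fit to the
feature points projected into the occlusal plane; inspection spokes —
realized as arc-length gaps along the fitted arch — split the points into
per-tooth groups, which are then assigned to the alternating constraint
sets Ω1 (odd groups, value 1) and Ω2 (even groups, value 0).

Sidecar format (one record per line, ``#`` comments allowed)::

    plane ox oy oz nx ny nz
    point x y z
    point x y z
    ...
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import ArchFitError, FeatureFormatError, SnapError
from .mesh import Plane, TriangleMesh

SNAP_TOL_MM = 0.5


@dataclass
class FeaturePointSet:
    """Feature points snapped onto mesh vertices."""

    points: np.ndarray  # (k, 3) snapped coordinates, mm
    vertex_ids: np.ndarray  # (k,) mesh vertex indices, unique

    def __len__(self):
        return len(self.vertex_ids)

    def subset(self, idx) -> "FeaturePointSet":
        idx = np.asarray(idx)
        return FeaturePointSet(self.points[idx].copy(), self.vertex_ids[idx].copy())


@dataclass
class ArchCurve:
    """Degree-4 polynomial arch in the occlusal-plane frame.

    ``frame`` maps 3D points into plane coordinates (u along the widest
    in-plane spread, v transverse); the curve is ``v = poly(u)``.
    """

    origin: np.ndarray
    axis_u: np.ndarray
    axis_v: np.ndarray
    normal: np.ndarray
    coeffs: np.ndarray  # numpy polyval order (highest power first)
    domain: tuple
    residual_rms: float

    def project(self, points: np.ndarray) -> np.ndarray:
        """(u, v) coordinates of points projected into the plane frame."""
        rel = np.asarray(points).reshape(-1, 3) - self.origin
        return np.stack([rel @ self.axis_u, rel @ self.axis_v], axis=1)

    def evaluate(self, u: np.ndarray) -> np.ndarray:
        """3D points on the arch at frame abscissae ``u``."""
        u = np.atleast_1d(np.asarray(u, dtype=float))
        v = np.polyval(self.coeffs, u)
        return self.origin + u[:, None] * self.axis_u + v[:, None] * self.axis_v

    def arc_samples(self, n: int = 2000, margin: float = 0.05):
        """Dense arch samples and cumulative arc length over the domain."""
        lo, hi = self.domain
        span = hi - lo
        u = np.linspace(lo - margin * span, hi + margin * span, n)
        pts = self.evaluate(u)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        return u, pts, s


@dataclass
class FeaturePointGroups:
    """Ordered per-tooth feature groups and the alternating Ω1/Ω2 split.

    Groups are 1-based along the arch; Ω1 is the union of odd-index
    groups (1, 3, 5, ...) and Ω2 of even-index groups, so adjacent teeth
    always land in different Dirichlet constraint sets.
    """

    groups: list  # list[FeaturePointSet], arch order
    arc_positions: list  # list[np.ndarray] arc-length parameters per group

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def omega1(self) -> np.ndarray:
        """Vertex ids of odd-index (1-based) groups."""
        sel = [g.vertex_ids for i, g in enumerate(self.groups) if i % 2 == 0]
        return np.concatenate(sel) if sel else np.empty(0, dtype=np.int64)

    @property
    def omega2(self) -> np.ndarray:
        """Vertex ids of even-index (1-based) groups."""
        sel = [g.vertex_ids for i, g in enumerate(self.groups) if i % 2 == 1]
        return np.concatenate(sel) if sel else np.empty(0, dtype=np.int64)

    def parity(self, group_index: int) -> int:
        """Constraint value (0 or 1) of the 0-based ``group_index``."""
        return 1 if group_index % 2 == 0 else 0


# ----------------------------------------------------------------------
def snap_to_mesh(points: np.ndarray, mesh: TriangleMesh,
                 tol: float = SNAP_TOL_MM) -> FeaturePointSet:
    """Snap raw feature coordinates to their nearest mesh vertices."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    tree = cKDTree(mesh.vertices)
    dist, vid = tree.query(points)
    if (dist > tol).any():
        bad = np.nonzero(dist > tol)[0]
        raise SnapError(
            f"feature points {bad.tolist()} are farther than {tol} mm from the mesh "
            f"(max distance {dist.max():.3f} mm)"
        )
    vid = np.asarray(vid, dtype=np.int64)
    if len(np.unique(vid)) != len(vid):
        # collapse duplicates deterministically, keeping first occurrences
        _, first = np.unique(vid, return_index=True)
        keep = np.sort(first)
        vid = vid[keep]
    return FeaturePointSet(points=mesh.vertices[vid].copy(), vertex_ids=vid)


def load_features(path, mesh: TriangleMesh) -> tuple[FeaturePointSet, Plane]:
    """Read the feature sidecar and snap its points onto the mesh.

    The returned occlusal normal is normalized and oriented so that the
    mean feature point lies on its positive side (occlusal side up).
    """
    path = Path(path)
    if not path.exists():
        raise FeatureFormatError(f"no such sidecar file: {path}")
    raw_points = []
    plane = None
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        try:
            if tokens[0] == "plane":
                vals = [float(t) for t in tokens[1:7]]
                if len(vals) != 6:
                    raise ValueError
                plane = Plane(vals[:3], vals[3:])
            elif tokens[0] == "point":
                vals = [float(t) for t in tokens[1:4]]
                if len(vals) != 3:
                    raise ValueError
                raw_points.append(vals)
            else:
                raise ValueError
        except (ValueError, IndexError):
            raise FeatureFormatError(f"{path}:{ln}: malformed record: {line!r}") from None
    if plane is None:
        raise FeatureFormatError(f"{path}: missing occlusal plane record")
    if not raw_points:
        raise FeatureFormatError(f"{path}: no feature points")
    features = snap_to_mesh(np.asarray(raw_points), mesh)
    if np.mean(plane.signed_distance(features.points)) < 0:
        plane = Plane(plane.origin, -plane.normal)
    return features, plane


def write_feature_sidecar(path, points: np.ndarray, plane: Plane) -> None:
    """Write feature points and the occlusal plane in sidecar format."""
    lines = ["# dentalseg feature sidecar"]
    o, n = plane.origin, plane.normal
    lines.append(f"plane {o[0]:.9g} {o[1]:.9g} {o[2]:.9g} {n[0]:.9g} {n[1]:.9g} {n[2]:.9g}")
    for p in np.asarray(points).reshape(-1, 3):
        lines.append(f"point {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}")
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
def fit_arch(features: FeaturePointSet, occlusal: Plane) -> ArchCurve:
    """Fit the degree-4 dental-arch curve in the occlusal plane.

    Feature points are projected onto the plane; the first frame axis is
    the in-plane direction of widest spread (principal axis), and
    ``v = p(u)`` is least-squares fit.
    """
    pts = features.points
    if len(pts) < 6:
        raise ArchFitError(f"need at least 6 feature points, got {len(pts)}")
    n = occlusal.normal
    rel = pts - occlusal.origin
    proj = rel - np.outer(rel @ n, n)
    center = proj.mean(axis=0)
    centered = proj - center
    # principal in-plane direction
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis_u = vt[0]
    axis_u = axis_u - (axis_u @ n) * n
    axis_u /= np.linalg.norm(axis_u)
    # deterministic orientation of the frame
    flip = axis_u[np.argmax(np.abs(axis_u))]
    if flip < 0:
        axis_u = -axis_u
    axis_v = np.cross(n, axis_u)
    origin = occlusal.origin + center
    u = centered @ axis_u
    v = centered @ axis_v
    if len(np.unique(np.round(u, 9))) < 5:
        raise ArchFitError("fewer than 5 distinct abscissae; degree-4 fit is rank deficient")
    coeffs = np.polyfit(u, v, deg=4)
    resid = v - np.polyval(coeffs, u)
    rms = float(np.sqrt(np.mean(resid**2)))
    return ArchCurve(
        origin=origin, axis_u=axis_u, axis_v=axis_v, normal=n.copy(),
        coeffs=coeffs, domain=(float(u.min()), float(u.max())), residual_rms=rms,
    )


def group_by_spokes(
    features: FeaturePointSet, arch: ArchCurve, gap_threshold: float = 3.0
) -> FeaturePointGroups:
    """Split feature points into per-tooth groups along the arch.

    Each point gets the arc-length parameter of its closest arch sample;
    an inspection spoke (group boundary) is placed at every gap between
    consecutive parameters larger than ``gap_threshold`` mm.
    """
    if len(features) == 0:
        return FeaturePointGroups(groups=[], arc_positions=[])
    _, curve_pts, s = arch.arc_samples()
    tree = cKDTree(curve_pts)
    _, nearest = tree.query(features.points)
    params = s[nearest]
    order = np.argsort(params, kind="stable")
    sorted_params = params[order]
    breaks = np.nonzero(np.diff(sorted_params) > gap_threshold)[0]
    groups = []
    positions = []
    start = 0
    for b in np.concatenate([breaks, [len(order) - 1]]):
        sel = order[start: b + 1]
        groups.append(features.subset(sel))
        positions.append(params[sel])
        start = b + 1
    return FeaturePointGroups(groups=groups, arc_positions=positions)
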