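"""Triangle-mesh data model, I/O, and differential-geometry primitives.

The :class:`TriangleMesh` is the domain of every computation in the
pipeline: an indexed vertex/face surface (coordinates in mm,
counter-clockwise faces) with cached adjacency.  On top of it this module
provides the discrete operators the segmentation needs:

* cotangent edge weights ``(cot α + cot β)/2`` for the Laplacian,
* signed dihedral angles (positive = convex) for concavity detection,
* principal curvatures by local quadric fitting,
* plane-mesh intersection loops and exact plane clipping.

File reading/writing of OBJ/PLY/STL goes through :mod:`trimesh`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import trimesh as _tm

from .errors import (
    ClipError,
    EdgeLookupError,
    MeshFormatError,
    MeshValidationError,
    UndefinedDihedralError,
)

_AREA_TOL = 1e-12  # mm^2; faces below this are degenerate
_STL_WELD_TOL = 1e-6  # mm; vertex welding tolerance for STL input


@dataclass(frozen=True)
class Plane:
    """Oriented plane: ``origin`` (mm) and unit ``normal``."""

    origin: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        o = np.asarray(self.origin, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("plane normal must be nonzero")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "normal", n / norm)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance of ``points`` (positive on the normal side)."""
        return np.asarray(points).reshape(-1, 3).dot(self.normal) - self.origin.dot(self.normal)

    def offset(self, distance: float) -> "Plane":
        """Parallel plane shifted by ``distance`` along the normal."""
        return Plane(self.origin + distance * self.normal, self.normal)


@dataclass
class IntersectionLoop:
    """Ordered polyline where a level set / plane crosses mesh edges.

    ``edge_refs[k] = (edge_id, t)`` places ``points[k]`` on mesh edge
    ``edges[edge_id] = (a, b)`` at parameter ``t`` from ``a`` to ``b``.
    """

    points: np.ndarray
    edge_refs: list
    closed: bool

    def __len__(self):
        return len(self.points)

    @property
    def length(self) -> float:
        p = self.points
        if len(p) < 2:
            return 0.0
        seg = np.linalg.norm(np.diff(p, axis=0), axis=1).sum()
        if self.closed:
            seg += np.linalg.norm(p[0] - p[-1])
        return float(seg)


@dataclass
class CurvatureField:
    """Per-vertex principal curvatures (1/mm), ``k_min <= k_max``."""

    k_min: np.ndarray
    k_max: np.ndarray


class TriangleMesh:
    """Manifold, nondegenerate triangle surface mesh.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array, CCW orientation, 0-based
    validate : bool
        Run full invariant validation on construction.
    """

    def __init__(self, vertices, faces, validate: bool = True):
        self.vertices = np.ascontiguousarray(vertices, dtype=float).reshape(-1, 3)
        self.faces = np.ascontiguousarray(faces, dtype=np.int64).reshape(-1, 3)
        self._cache: dict = {}
        if validate:
            self.validate()

    # ------------------------------------------------------------------
    # basic properties
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def _edge_data(self):
        if "edge_data" not in self._cache:
            # half-edges in face order (0,1),(1,2),(2,0)
            he = self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
            he_sorted = np.sort(he, axis=1)
            edges, inv, counts = np.unique(
                he_sorted, axis=0, return_inverse=True, return_counts=True
            )
            self._cache["edge_data"] = (edges, inv.ravel(), counts)
        return self._cache["edge_data"]

    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges, each row sorted ``(a, b)`` with a < b."""
        return self._edge_data()[0]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def edge_index(self) -> dict:
        """Map ``(a, b)`` (a < b) -> edge id."""
        if "edge_index" not in self._cache:
            self._cache["edge_index"] = {
                (int(a), int(b)): i for i, (a, b) in enumerate(self.edges)
            }
        return self._cache["edge_index"]

    @property
    def face_edge_ids(self) -> np.ndarray:
        """(m, 3) edge ids of the face edges (0,1),(1,2),(2,0)."""
        return self._edge_data()[1].reshape(-1, 3)

    @property
    def edge_faces(self) -> np.ndarray:
        """(E, 2) adjacent face ids per edge; -1 marks a missing side."""
        if "edge_faces" not in self._cache:
            edges, inv, _ = self._edge_data()
            ef = np.full((len(edges), 2), -1, dtype=np.int64)
            face_of = np.repeat(np.arange(self.n_faces), 3)
            slot = np.zeros(len(edges), dtype=np.int64)
            # deterministic: first face touching an edge goes to slot 0
            for e, f in zip(inv, face_of):
                ef[e, slot[e]] = f
                slot[e] += 1
            self._cache["edge_faces"] = ef
        return self._cache["edge_faces"]

    @property
    def boundary_edge_mask(self) -> np.ndarray:
        return self.edge_faces[:, 1] < 0

    @property
    def boundary_vertices(self) -> np.ndarray:
        """Sorted indices of vertices on boundary edges."""
        if "boundary_vertices" not in self._cache:
            be = self.edges[self.boundary_edge_mask]
            self._cache["boundary_vertices"] = np.unique(be)
        return self._cache["boundary_vertices"]

    @property
    def face_normals(self) -> np.ndarray:
        if "face_normals" not in self._cache:
            v = self.vertices
            f = self.faces
            n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
            norm = np.linalg.norm(n, axis=1)
            norm = np.where(norm == 0, 1.0, norm)
            self._cache["face_normals"] = n / norm[:, None]
        return self._cache["face_normals"]

    @property
    def face_areas(self) -> np.ndarray:
        if "face_areas" not in self._cache:
            v = self.vertices
            f = self.faces
            n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
            self._cache["face_areas"] = 0.5 * np.linalg.norm(n, axis=1)
        return self._cache["face_areas"]

    @property
    def vertex_normals(self) -> np.ndarray:
        """Area-weighted average of incident face normals, unit length."""
        if "vertex_normals" not in self._cache:
            vn = np.zeros_like(self.vertices)
            w = self.face_normals * self.face_areas[:, None]
            for k in range(3):
                np.add.at(vn, self.faces[:, k], w)
            norm = np.linalg.norm(vn, axis=1)
            norm = np.where(norm == 0, 1.0, norm)
            self._cache["vertex_normals"] = vn / norm[:, None]
        return self._cache["vertex_normals"]

    @property
    def vertex_adjacency(self) -> sp.csr_matrix:
        """Symmetric boolean vertex adjacency (1-ring structure)."""
        if "vertex_adjacency" not in self._cache:
            e = self.edges
            n = self.n_vertices
            data = np.ones(len(e), dtype=bool)
            a = sp.coo_matrix((data, (e[:, 0], e[:, 1])), shape=(n, n))
            a = (a + a.T).tocsr()
            self._cache["vertex_adjacency"] = a
        return self._cache["vertex_adjacency"]

    def one_ring(self, i: int) -> np.ndarray:
        """1-ring neighbor vertex indices of vertex ``i``."""
        a = self.vertex_adjacency
        return a.indices[a.indptr[i]: a.indptr[i + 1]]

    def euler_characteristic(self) -> int:
        return self.n_vertices - self.n_edges + self.n_faces

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`MeshValidationError` on any invariant violation."""
        f = self.faces
        if f.size and (f.min() < 0 or f.max() >= self.n_vertices):
            raise MeshValidationError("face indices out of vertex range")
        repeated = (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
        if repeated.any():
            bad = np.nonzero(repeated)[0][:10]
            raise MeshValidationError(f"faces with repeated vertex index: {bad.tolist()}")
        degen = self.face_areas < _AREA_TOL
        if degen.any():
            bad = np.nonzero(degen)[0][:10]
            raise MeshValidationError(f"zero-area faces below {_AREA_TOL} mm^2: {bad.tolist()}")
        _, _, counts = self._edge_data()
        if (counts > 2).any():
            bad_edges = self.edges[counts > 2][:10]
            raise MeshValidationError(
                f"non-manifold edges shared by >2 faces: {bad_edges.tolist()}"
            )

    # ------------------------------------------------------------------
    # differential geometry
    def _corner_cotangents(self) -> np.ndarray:
        """(m, 3) cotangent of the interior angle at each face corner."""
        if "corner_cot" not in self._cache:
            v = self.vertices
            f = self.faces
            cots = np.empty((self.n_faces, 3))
            for c in range(3):
                p0 = v[f[:, c]]
                p1 = v[f[:, (c + 1) % 3]]
                p2 = v[f[:, (c + 2) % 3]]
                u = p1 - p0
                w = p2 - p0
                cross = np.linalg.norm(np.cross(u, w), axis=1)
                cross = np.where(cross == 0, 1e-300, cross)
                cots[:, c] = (u * w).sum(axis=1) / cross
            self._cache["corner_cot"] = cots
        return self._cache["corner_cot"]

    def cotangent_weights(self) -> np.ndarray:
        """Per-edge cotangent weights ``(cot α + cot β)/2``.

        Boundary edges use the single available opposite angle halved.
        """
        if "cot_weights" not in self._cache:
            _, inv, _ = self._edge_data()
            # edge (c+1, c+2) of a face is opposite corner c:
            # half-edges are ordered (0,1),(1,2),(2,0) -> opposite corners 2,0,1
            cots = self._corner_cotangents()[:, [2, 0, 1]].ravel()
            sums = np.zeros(self.n_edges)
            np.add.at(sums, inv, cots)
            self._cache["cot_weights"] = sums / 2.0
        return self._cache["cot_weights"]

    def _lookup_edge(self, edge) -> int:
        key = (int(min(edge)), int(max(edge)))
        try:
            return self.edge_index[key]
        except KeyError:
            raise EdgeLookupError(f"edge {key} not in mesh") from None

    def cotangent_weight(self, edge) -> float:
        """Cotangent weight of a single edge (vertex-index pair)."""
        return float(self.cotangent_weights()[self._lookup_edge(edge)])

    def dihedral_angles(self) -> np.ndarray:
        """Signed dihedral angle per edge (radians); NaN on boundary edges.

        Convention: 0 for coplanar faces, positive where the surface is
        convex across the edge (outward normals diverge), negative where
        it is concave.
        """
        if "dihedral" not in self._cache:
            ef = self.edge_faces
            interior = ef[:, 1] >= 0
            ang = np.full(self.n_edges, np.nan)
            f0 = ef[interior, 0]
            f1 = ef[interior, 1]
            n0 = self.face_normals[f0]
            n1 = self.face_normals[f1]
            e = self.edges[interior]
            # orient the edge as it appears (CCW) in face f0
            faces0 = self.faces[f0]
            evec = self.vertices[e[:, 1]] - self.vertices[e[:, 0]]
            # does (a, b) appear as a forward half-edge of f0?
            fwd = (
                ((faces0[:, 0] == e[:, 0]) & (faces0[:, 1] == e[:, 1]))
                | ((faces0[:, 1] == e[:, 0]) & (faces0[:, 2] == e[:, 1]))
                | ((faces0[:, 2] == e[:, 0]) & (faces0[:, 0] == e[:, 1]))
            )
            evec = np.where(fwd[:, None], evec, -evec)
            elen = np.linalg.norm(evec, axis=1)
            elen = np.where(elen == 0, 1.0, elen)
            ehat = evec / elen[:, None]
            s = (np.cross(n0, n1) * ehat).sum(axis=1)
            c = (n0 * n1).sum(axis=1)
            ang[interior] = np.arctan2(s, np.clip(c, -1.0, 1.0))
            self._cache["dihedral"] = ang
        return self._cache["dihedral"]

    def dihedral_angle(self, edge) -> float:
        eid = self._lookup_edge(edge)
        ang = self.dihedral_angles()[eid]
        if np.isnan(ang):
            raise UndefinedDihedralError(f"edge {tuple(self.edges[eid])} is a boundary edge")
        return float(ang)

    # ------------------------------------------------------------------
    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(), validate=False)

    def to_trimesh(self) -> _tm.Trimesh:
        return _tm.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    def save(self, path) -> None:
        """Write the mesh in the format implied by the file suffix."""
        self.to_trimesh().export(str(path))


# ----------------------------------------------------------------------
# I/O
_FORMATS = {"obj", "ply", "stl"}


def load_mesh(path, fmt: str | None = None, validate: bool = True) -> TriangleMesh:
    """Load an OBJ/PLY/STL surface into a validated :class:`TriangleMesh`.

    Vertex order is preserved for OBJ/PLY; STL input (which stores
    per-triangle corners) is vertex-welded at 1e-6 mm.
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"no such file: {path}")
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise MeshFormatError(f"unsupported mesh format: {fmt!r}")
    try:
        raw = _tm.load(str(path), file_type=fmt, process=False, force="mesh")
    except Exception as exc:  # noqa: BLE001 - any parser failure is a format error
        raise MeshFormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    if not isinstance(raw, _tm.Trimesh) or len(raw.faces) == 0:
        raise MeshFormatError(f"{path} contains no triangle geometry")
    vertices = np.asarray(raw.vertices, dtype=float)
    faces = np.asarray(raw.faces, dtype=np.int64)
    if fmt == "stl":
        vertices, faces = weld_vertices(vertices, faces, tol=_STL_WELD_TOL)
    return TriangleMesh(vertices, faces, validate=validate)


def weld_vertices(vertices: np.ndarray, faces: np.ndarray, tol: float = _STL_WELD_TOL):
    """Merge vertices closer than ``tol`` (grid quantization)."""
    keys = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    # keep the first occurrence ordering
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    new_vertices = vertices[first[order]]
    new_faces = rank[inverse.ravel()][faces]
    keep = ~(
        (new_faces[:, 0] == new_faces[:, 1])
        | (new_faces[:, 1] == new_faces[:, 2])
        | (new_faces[:, 0] == new_faces[:, 2])
    )
    return new_vertices, new_faces[keep]


# ----------------------------------------------------------------------
# level-set tracing (shared by plane intersection and isoline extraction)
def trace_level_set(mesh: TriangleMesh, scalar: np.ndarray, level: float) -> list[IntersectionLoop]:
    """Trace the ``scalar == level`` curve(s) over the mesh surface.

    Returns one polyline per connected component, each point lying on a
    mesh edge with the crossing parameter recorded.  Components that do
    not touch the mesh boundary come back closed.
    """
    d = np.asarray(scalar, dtype=float) - level
    scale = max(float(np.abs(d).max(initial=0.0)), 1.0)
    # nudge exact zeros so every crossing is a proper sign change
    d = np.where(d == 0.0, 1e-14 * scale, d)
    pos = d > 0
    f = mesh.faces
    fp = pos[f]
    crossed = fp.any(axis=1) & ~fp.all(axis=1)
    if not crossed.any():
        return []
    cf = np.nonzero(crossed)[0]
    fe = mesh.face_edge_ids[cf]  # (k,3) edge ids for (0,1),(1,2),(2,0)
    sign = fp[cf]
    # which of the three face edges are crossed (exactly two per face)
    ecross = np.stack(
        [sign[:, 0] != sign[:, 1], sign[:, 1] != sign[:, 2], sign[:, 2] != sign[:, 0]],
        axis=1,
    )
    # gather (face, edge_id) pairs for crossed edges
    crossed_edge_ids = np.unique(fe[ecross])
    # crossing point per crossed edge (canonical orientation a < b)
    edges = mesh.edges
    a = edges[crossed_edge_ids, 0]
    b = edges[crossed_edge_ids, 1]
    t = d[a] / (d[a] - d[b])
    pts = mesh.vertices[a] + t[:, None] * (mesh.vertices[b] - mesh.vertices[a])
    point_of = dict(zip(crossed_edge_ids.tolist(), range(len(crossed_edge_ids))))

    # adjacency between crossed edges through crossed faces
    pair_rows = fe[ecross].reshape(-1, 2)  # two crossed edges per crossed face
    links: dict[int, list[int]] = {int(e): [] for e in crossed_edge_ids}
    for e1, e2 in pair_rows:
        links[int(e1)].append(int(e2))
        links[int(e2)].append(int(e1))

    visited: set[int] = set()
    loops: list[IntersectionLoop] = []

    def _walk(start: int) -> tuple[list[int], bool]:
        chain = [start]
        visited.add(start)
        prev = -1
        cur = start
        closed = False
        while True:
            nxt = None
            for e in links[cur]:
                if e == prev:
                    continue
                if e == start and len(chain) > 2:
                    closed = True
                    break
                if e not in visited:
                    nxt = e
                    break
            if closed or nxt is None:
                break
            visited.add(nxt)
            chain.append(nxt)
            prev, cur = cur, nxt
        return chain, closed

    # open polylines first (start at edges with a single link = boundary hit)
    endpoints = [e for e in crossed_edge_ids.tolist() if len(links[e]) < 2]
    for e in endpoints:
        if e in visited:
            continue
        chain, _ = _walk(e)
        loops.append(_make_loop(mesh, chain, False, point_of, pts, t, edges))
    # remaining components are cycles
    for e in crossed_edge_ids.tolist():
        if e in visited:
            continue
        chain, closed = _walk(e)
        loops.append(_make_loop(mesh, chain, closed, point_of, pts, t, edges))
    return loops


def _make_loop(mesh, chain, closed, point_of, pts, t, edges) -> IntersectionLoop:
    idx = [point_of[e] for e in chain]
    points = pts[idx]
    refs = [((int(edges[e, 0]), int(edges[e, 1])), float(t[point_of[e]])) for e in chain]
    return IntersectionLoop(points=points, edge_refs=refs, closed=closed)


def intersect_with_plane(mesh: TriangleMesh, plane: Plane) -> list[IntersectionLoop]:
    """All connected intersection polylines of ``plane`` with the surface."""
    scalar = plane.signed_distance(mesh.vertices)
    return trace_level_set(mesh, scalar, 0.0)


# ----------------------------------------------------------------------
# clipping
def clip_below_plane(mesh: TriangleMesh, plane: Plane) -> tuple[TriangleMesh, np.ndarray]:
    """Keep the part of the mesh on the plane's positive (occlusal) side.

    Triangles crossing the plane are split exactly at the plane; the newly
    created cut vertices (lying on the plane to within 1e-9 mm) are
    returned as the recorded loop vertex set.
    """
    v = mesh.vertices.copy()
    d = plane.signed_distance(v)
    on_tol = 1e-9  # mm; vertices this close count as lying on the plane
    sgn = np.where(d > on_tol, 1, np.where(d < -on_tol, -1, 0))
    # snap near-plane vertices exactly onto the plane
    on_plane = sgn == 0
    v[on_plane] -= d[on_plane, None] * plane.normal
    if (sgn > 0).all() or not (sgn > 0).any():
        raise ClipError("plane does not intersect the mesh")

    f = mesh.faces
    fs = sgn[f]
    n_pos = (fs > 0).sum(axis=1)
    n_neg = (fs < 0).sum(axis=1)

    next_id = mesh.n_vertices
    cut_vertex_of_edge: dict[int, int] = {}
    cut_points = []

    def _cut_vertex(va: int, vb: int) -> int:
        nonlocal next_id
        key = mesh.edge_index[(min(va, vb), max(va, vb))]
        if key in cut_vertex_of_edge:
            return cut_vertex_of_edge[key]
        a, b = mesh.edges[key]
        tt = d[a] / (d[a] - d[b])
        p = v[a] + tt * (v[b] - v[a])
        # project exactly onto the plane
        p = p - plane.signed_distance(p[None])[0] * plane.normal
        cut_points.append(p)
        cut_vertex_of_edge[key] = next_id
        next_id += 1
        return cut_vertex_of_edge[key]

    out_faces = list(f[n_neg == 0])
    for fi in np.nonzero((n_pos > 0) & (n_neg > 0))[0]:
        tri = f[fi]
        s = fs[fi]
        n_zero = int((s == 0).sum())
        if n_zero == 1:
            # one vertex on the plane: split the opposite (+,-) edge
            r = int(np.nonzero(s == 0)[0][0])
            z0, a, b = tri[r], tri[(r + 1) % 3], tri[(r + 2) % 3]
            x = _cut_vertex(a, b)
            if sgn[a] > 0:
                out_faces.append((z0, a, x))
            else:
                out_faces.append((z0, x, b))
        elif n_pos[fi] == 1:
            r = int(np.nonzero(s > 0)[0][0])
            a, b, c = tri[r], tri[(r + 1) % 3], tri[(r + 2) % 3]
            xab = _cut_vertex(a, b)
            xca = _cut_vertex(c, a)
            out_faces.append((a, xab, xca))
        else:
            r = int(np.nonzero(s < 0)[0][0])  # the single negative vertex
            c, a, b = tri[r], tri[(r + 1) % 3], tri[(r + 2) % 3]
            # a, b positive; c negative
            xbc = _cut_vertex(b, c)
            xca = _cut_vertex(c, a)
            out_faces.append((a, b, xbc))
            out_faces.append((a, xbc, xca))

    all_vertices = np.vstack([v] + ([np.asarray(cut_points)] if cut_points else []))
    out_faces = np.asarray(out_faces, dtype=np.int64)

    # compact to referenced vertices only
    used = np.unique(out_faces)
    remap = np.full(len(all_vertices), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    clipped = TriangleMesh(all_vertices[used], remap[out_faces], validate=False)
    # recorded loop: the newly created cut vertices plus any original
    # vertices that lay on the plane and survive in the clipped mesh
    loop_ids = np.concatenate(
        [np.arange(mesh.n_vertices, next_id), np.nonzero(on_plane)[0]]
    )
    omega3 = remap[loop_ids.astype(np.int64)]
    omega3 = np.unique(omega3[omega3 >= 0])
    return clipped, omega3


# ----------------------------------------------------------------------
# curvature
def principal_curvatures(mesh: TriangleMesh, ring_radius: int = 2) -> CurvatureField:
    """Per-vertex principal curvatures by quadric fitting.

    A height function over the vertex tangent plane is least-squares fit
    with a full quadric ``h = q0 x^2 + q1 xy + q2 y^2 + q3 x + q4 y`` over
    the ``ring_radius``-ring neighborhood; the shape operator of the graph
    gives (k_min, k_max).  Sign convention: a convex bump relative to the
    outward normal has positive curvatures.
    """
    if ring_radius < 1:
        raise ValueError("ring_radius must be >= 1")
    n = mesh.n_vertices
    adj = mesh.vertex_adjacency
    ring = adj.copy().astype(bool)
    power = adj.astype(bool)
    for _ in range(ring_radius - 1):
        power = (power @ adj).astype(bool)
        ring = (ring + power).astype(bool)
    ring = sp.csr_matrix(ring)
    ring.setdiag(False)
    ring.eliminate_zeros()
    coo = ring.tocoo()
    vi = coo.row
    vj = coo.col

    normals = mesh.vertex_normals
    # tangent frames
    ref = np.tile(np.array([1.0, 0.0, 0.0]), (n, 1))
    degenerate = np.abs(normals[:, 0]) > 0.9
    ref[degenerate] = [0.0, 1.0, 0.0]
    t1 = np.cross(normals, ref)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(normals, t1)

    dvec = mesh.vertices[vj] - mesh.vertices[vi]
    x = (dvec * t1[vi]).sum(axis=1)
    y = (dvec * t2[vi]).sum(axis=1)
    h = (dvec * normals[vi]).sum(axis=1)

    design = np.stack([x * x, x * y, y * y, x, y], axis=1)  # (p, 5)
    ata = np.zeros((n, 5, 5))
    atb = np.zeros((n, 5))
    chunk = 200_000
    for s0 in range(0, len(vi), chunk):
        sl = slice(s0, s0 + chunk)
        dd = design[sl]
        np.add.at(ata, vi[sl], dd[:, :, None] * dd[:, None, :])
        np.add.at(atb, vi[sl], dd * h[sl, None])

    counts = np.bincount(vi, minlength=n)
    # ridge keeps rank-deficient neighborhoods solvable
    tr = np.einsum("nii->n", ata)
    ridge = np.maximum(tr, 1.0) * 1e-12
    ata += ridge[:, None, None] * np.eye(5)[None]
    q = np.linalg.solve(ata, atb[..., None])[..., 0]

    isolated = counts < 5
    if isolated.any():
        warnings.warn(
            f"{int(isolated.sum())} vertices with <5 ring neighbors; curvature set to 0",
            stacklevel=2,
        )
        q[isolated] = 0.0

    gx, gy = q[:, 3], q[:, 4]
    denom = np.sqrt(1.0 + gx * gx + gy * gy)
    # second fundamental form (w.r.t. outward normal) and metric
    l11 = 2.0 * q[:, 0] / denom
    l12 = q[:, 1] / denom
    l22 = 2.0 * q[:, 2] / denom
    g11 = 1.0 + gx * gx
    g12 = gx * gy
    g22 = 1.0 + gy * gy
    det_g = g11 * g22 - g12 * g12
    # shape operator S = G^{-1} II ; eigenvalues from trace/determinant
    s11 = (g22 * l11 - g12 * l12) / det_g
    s12 = (g22 * l12 - g12 * l22) / det_g
    s21 = (-g12 * l11 + g11 * l12) / det_g
    s22 = (-g12 * l12 + g11 * l22) / det_g
    tr_s = s11 + s22
    det_s = s11 * s22 - s12 * s21
    disc = np.sqrt(np.maximum(tr_s * tr_s - 4.0 * det_s, 0.0))
    k1 = 0.5 * (tr_s + disc)
    k2 = 0.5 * (tr_s - disc)
    # graph height was measured along the outward normal: a convex bump has
    # negative Hessian there, so negate to make convex positive
    ka = -k1
    kb = -k2
    k_min = np.minimum(ka, kb)
    k_max = np.maximum(ka, kb)
    k_min[isolated] = 0.0
    k_max[isolated] = 0.0
    return CurvatureField(k_min=k_min, k_max=k_max)
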