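"""Tooth boundary extraction from the harmonic field.

Isolines of Φ are sampled uniformly in the two parity bands (0, 0.5) and
(0.5, 1) — every tooth boundary must separate that tooth's constraint
value (0 or 1) from the 0.5 gingiva contour, so candidates for a
parity-1 tooth live above 0.5 and for a parity-0 tooth below it.  Closed
isoloops that enclose exactly one tooth's feature points are candidates
for that tooth; a voting score — the mean positive concavity of the
minimum principal curvature along the loop — selects the isoloop best
seated in the concave interstitial/gingival grooves (the minima rule).
The winning loops induce the final per-face labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .errors import BoundaryTopologyError, ScoringError
from .features import FeaturePointGroups
from .harmonic import HarmonicField
from .mesh import CurvatureField, IntersectionLoop, TriangleMesh, trace_level_set

DEFAULT_N_LEVELS = 50
_INTERP_TOL = 1e-10


@dataclass
class IsoLoop:
    """A level-set polyline of the harmonic field on mesh edges."""

    level: float
    points: np.ndarray
    edge_refs: list
    closed: bool
    enclosed_groups: frozenset = frozenset()
    region_mask: np.ndarray | None = None  # vertices of the enclosed region

    def __len__(self):
        return len(self.points)

    @property
    def length(self) -> float:
        p = self.points
        if len(p) < 2:
            return 0.0
        total = np.linalg.norm(np.diff(p, axis=0), axis=1).sum()
        if self.closed:
            total += np.linalg.norm(p[0] - p[-1])
        return float(total)


@dataclass
class SegmentationResult:
    """Final per-face labels (0 = gingiva/base, 1..K teeth) and boundaries."""

    labels: np.ndarray
    boundaries: dict  # tooth id -> IsoLoop (present teeth only)
    flagged: list  # tooth ids with no candidate boundary

    @property
    def n_teeth(self) -> int:
        return len(self.boundaries)


# ----------------------------------------------------------------------
def extract_isolines(
    mesh: TriangleMesh, field_: HarmonicField, levels
) -> list[IsoLoop]:
    """Marching-triangles isolines of Φ at each requested level."""
    phi = field_.phi
    out: list[IsoLoop] = []
    for level in np.atleast_1d(np.asarray(levels, dtype=float)):
        for lp in trace_level_set(mesh, phi, float(level)):
            out.append(
                IsoLoop(
                    level=float(level),
                    points=lp.points,
                    edge_refs=lp.edge_refs,
                    closed=lp.closed,
                )
            )
    return out


def _region_components(mesh: TriangleMesh, phi: np.ndarray, level: float, above: bool):
    """Connected components of the super/sub level set of Φ."""
    mask = phi > level if above else phi < level
    adj = mesh.vertex_adjacency
    sub = adj[mask][:, mask]
    n_comp, labels = connected_components(sub, directed=False)
    full = np.full(mesh.n_vertices, -1, dtype=np.int64)
    full[mask] = labels
    return full


def annotate_enclosure(
    mesh: TriangleMesh,
    field_: HarmonicField,
    loops: list[IsoLoop],
    groups: FeaturePointGroups,
) -> None:
    """Attach the enclosed region and enclosed feature groups to each loop.

    The enclosed region of a closed isoloop is the level-set side that
    does not reach the mesh boundary (the side "away from" the gingiva
    cut).  A loop encloses group g when every feature vertex of g lies in
    that region.
    """
    phi = field_.phi
    boundary = np.zeros(mesh.n_vertices, dtype=bool)
    boundary[mesh.boundary_vertices] = True
    by_level: dict[float, list[IsoLoop]] = {}
    for lp in loops:
        by_level.setdefault(lp.level, []).append(lp)
    for level, lvl_loops in by_level.items():
        comp_above = _region_components(mesh, phi, level, above=True)
        comp_below = _region_components(mesh, phi, level, above=False)
        # region key -> (loop, mask); only the longest loop bounding a
        # region is its outer contour and carries the enclosure
        region_owner: dict[tuple, IsoLoop] = {}
        assigned: dict[tuple, np.ndarray] = {}
        for lp in lvl_loops:
            lp.enclosed_groups = frozenset()
            if not lp.closed:
                continue
            # side vertices adjacent to the loop
            (a0, b0), _t = lp.edge_refs[0]
            hi_v = a0 if phi[a0] > level else b0
            lo_v = b0 if hi_v == a0 else a0
            candidates = []
            c_hi = comp_above[hi_v]
            if c_hi >= 0:
                candidates.append((("above", int(c_hi)), comp_above == c_hi))
            c_lo = comp_below[lo_v]
            if c_lo >= 0:
                candidates.append((("below", int(c_lo)), comp_below == c_lo))
            # enclosed side: does not touch the mesh boundary
            inside = [(k, m) for k, m in candidates if not (m & boundary).any()]
            if not inside:
                continue
            key, mask = min(inside, key=lambda km: km[1].sum())
            cur = region_owner.get(key)
            if cur is None or lp.length > cur.length:
                region_owner[key] = lp
                assigned[key] = mask
        for key, lp in region_owner.items():
            mask = assigned[key]
            enclosed = set()
            for gi, g in enumerate(groups.groups):
                if mask[g.vertex_ids].all():
                    enclosed.add(gi)
            lp.enclosed_groups = frozenset(enclosed)
            lp.region_mask = mask


def candidate_loops(
    loops: list[IsoLoop], group_index: int, parity: int
) -> list[IsoLoop]:
    """Closed loops enclosing exactly this group, in this parity's band."""
    out = []
    for lp in loops:
        if not lp.closed:
            continue
        in_band = lp.level > 0.5 if parity == 1 else lp.level < 0.5
        if in_band and lp.enclosed_groups == frozenset({group_index}):
            out.append(lp)
    return out


def score_loop(
    mesh: TriangleMesh, loop: IsoLoop, curvature: CurvatureField
) -> float:
    """Voting score: mean positive concavity (1/len) ∮ max(0, −k_min) ds.

    Loops seated in concave grooves score high; loops over flat or convex
    terrain score ~0.
    """
    if not loop.closed:
        raise ScoringError("loop score is defined for closed loops only")
    k = curvature.k_min
    vals = np.array([(1.0 - t) * k[a] + t * k[b] for (a, b), t in loop.edge_refs])
    concavity = np.maximum(0.0, -vals)
    pts = loop.points
    nxt = np.roll(np.arange(len(pts)), -1)
    seg = np.linalg.norm(pts[nxt] - pts, axis=1)
    # per-segment trapezoid of endpoint concavities
    seg_c = 0.5 * (concavity + concavity[nxt])
    total = seg.sum()
    if total == 0:
        return 0.0
    return float((seg_c * seg).sum() / total)


def select_boundaries(
    mesh: TriangleMesh,
    field_: HarmonicField,
    groups: FeaturePointGroups,
    curvature: CurvatureField,
    n_levels: int = DEFAULT_N_LEVELS,
) -> tuple[dict, list]:
    """Optimal isoloop per tooth group.

    Samples ``n_levels`` uniform levels in each parity band, keeps the
    candidates of each tooth, and returns the argmax-score loop per
    tooth.  Ties break toward the level farther from the tooth's
    constraint value (the larger enclosed region).  Returns
    ``(boundaries, flagged)`` where flagged lists tooth ids (1-based)
    with no candidate.
    """
    if n_levels < 3:
        raise ValueError("n_levels must be >= 3")
    frac = np.arange(1, n_levels + 1) / (n_levels + 1)
    lower = 0.5 * frac  # (0, 0.5)
    upper = 0.5 + 0.5 * frac  # (0.5, 1)
    loops = extract_isolines(mesh, field_, np.concatenate([lower, upper]))
    annotate_enclosure(mesh, field_, loops, groups)

    boundaries: dict[int, IsoLoop] = {}
    flagged: list[int] = []
    for gi in range(groups.n_groups):
        parity = groups.parity(gi)
        cands = candidate_loops(loops, gi, parity)
        tooth_id = gi + 1
        if not cands:
            flagged.append(tooth_id)
            continue
        scores = np.array([score_loop(mesh, lp, curvature) for lp in cands])
        best = scores.max()
        tied = [lp for lp, s in zip(cands, scores) if s >= best - 1e-12]
        constraint_value = float(parity)
        winner = max(tied, key=lambda lp: abs(lp.level - constraint_value))
        boundaries[tooth_id] = winner
    return boundaries, flagged


def _crossed_edge_ids(mesh: TriangleMesh, loop: IsoLoop) -> set:
    idx = mesh.edge_index
    return {idx[ref[0]] for ref in loop.edge_refs}


def label_faces(
    mesh: TriangleMesh,
    boundaries: dict,
    groups: FeaturePointGroups,
) -> SegmentationResult:
    """Per-face segmentation labels induced by the tooth boundaries.

    Faces with a vertex inside tooth k's enclosed region get label k
    (boundary-crossed faces therefore fall to the tooth side); everything
    else is the non-teeth part, label 0.  Boundaries must be pairwise
    non-crossing: their enclosed vertex regions may not partially overlap
    (loops of adjacent teeth may legally pass through the same mesh edge
    where the field jumps across an interstice, at different parameters).
    """
    ids = sorted(boundaries)
    for i, ta in enumerate(ids):
        ma = boundaries[ta].region_mask
        if ma is None:
            continue
        for tb in ids[i + 1:]:
            mb = boundaries[tb].region_mask
            if mb is None:
                continue
            inter = ma & mb
            if inter.any() and not (inter.sum() in (ma.sum(), mb.sum())):
                raise BoundaryTopologyError(
                    f"boundaries of teeth {ta} and {tb} cross (regions partially overlap)"
                )

    labels = np.zeros(mesh.n_faces, dtype=np.int64)
    claim_count = np.zeros(mesh.n_faces, dtype=np.int64)
    for tooth_id, lp in boundaries.items():
        mask = lp.region_mask
        if mask is None:
            continue
        in_face = mask[mesh.faces].sum(axis=1)
        claim = in_face > 0
        better = claim & (in_face > claim_count)
        labels[better] = tooth_id
        claim_count[better] = in_face[better]
    return SegmentationResult(
        labels=labels, boundaries=dict(boundaries), flagged=[]
    )


def interpolation_exactness(field_: HarmonicField, loop: IsoLoop) -> float:
    """Max |(1-t)Φ_a + tΦ_b − level| over the loop's points (should be ~0)."""
    phi = field_.phi
    errs = [
        abs((1.0 - t) * phi[a] + t * phi[b] - loop.level)
        for (a, b), t in loop.edge_refs
    ]
    return max(errs) if errs else 0.0
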