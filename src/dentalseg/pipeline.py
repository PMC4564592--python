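"""One-command pipeline: load -> features -> gingiva cut -> harmonic field
-> boundary extraction -> export, plus the evaluation metrics.

The stages mirror the segmentation framework's block diagram: anatomical
feature points and the occlusal plane are the a-priori knowledge; a
curvature-variance plane sweep removes the gingival base and records the
cut contour; the concavity-aware harmonic field with alternating 0/1
tooth constraints and the 0.5 contour is solved once for all teeth; and
one optimal isoloop per tooth becomes its boundary.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial import cKDTree

from . import boundary as _boundary
from . import features as _features
from . import gingiva as _gingiva
from . import harmonic as _harmonic
from .errors import ConfigError, EvaluationError
from .mesh import Plane, TriangleMesh, load_mesh, principal_curvatures

log = logging.getLogger("dentalseg")


# ----------------------------------------------------------------------
# configuration
@dataclass
class SweepConfig:
    step_mm: float = 1.0
    min_loop_points: int = 8
    energy_threshold: float = 0.5


@dataclass
class HarmonicConfig:
    w: float = 1000.0
    epsilon: float = 0.05
    concave_tol_rad: float = 0.10
    gamma_mode: str = "smooth"
    sigma: float = 0.1


@dataclass
class BoundaryConfig:
    n_levels: int = 50


@dataclass
class FeatureConfig:
    gap_threshold_mm: float = 3.0


@dataclass
class CurvatureConfig:
    ring_radius: int = 2


@dataclass
class PipelineConfig:
    """Validated configuration of the whole pipeline."""

    mesh_path: str = ""
    features_path: str = ""
    output_dir: str = "dentalseg_out"
    log_level: str = "INFO"
    seed: int = 0
    sweep: SweepConfig = dc_field(default_factory=SweepConfig)
    harmonic: HarmonicConfig = dc_field(default_factory=HarmonicConfig)
    boundary: BoundaryConfig = dc_field(default_factory=BoundaryConfig)
    features: FeatureConfig = dc_field(default_factory=FeatureConfig)
    curvature: CurvatureConfig = dc_field(default_factory=CurvatureConfig)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        """Build from a (possibly nested) dict, rejecting unknown keys."""
        sections = {
            "sweep": SweepConfig,
            "harmonic": HarmonicConfig,
            "boundary": BoundaryConfig,
            "features": FeatureConfig,
            "curvature": CurvatureConfig,
        }
        scalars = {"mesh_path", "features_path", "output_dir", "log_level", "seed"}
        kwargs: dict = {}
        for key, value in raw.items():
            if key in sections:
                sect_cls = sections[key]
                valid = set(sect_cls.__dataclass_fields__)
                unknown = set(value) - valid
                if unknown:
                    raise ConfigError(f"unknown config keys in '{key}': {sorted(unknown)}")
                kwargs[key] = sect_cls(**value)
            elif key in scalars:
                kwargs[key] = value
            else:
                raise ConfigError(f"unknown config key: {key!r}")
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(raw)

    def validate(self) -> None:
        if self.sweep.step_mm <= 0:
            raise ConfigError("sweep.step_mm must be positive")
        if not 0 < self.harmonic.epsilon <= 1:
            raise ConfigError("harmonic.epsilon must lie in (0, 1]")
        if self.harmonic.gamma_mode not in ("binary", "smooth"):
            raise ConfigError("harmonic.gamma_mode must be binary|smooth")
        if self.boundary.n_levels < 3:
            raise ConfigError("boundary.n_levels must be >= 3")
        if self.curvature.ring_radius < 1:
            raise ConfigError("curvature.ring_radius must be >= 1")

    def weight_params(self) -> _harmonic.EdgeWeightParams:
        return _harmonic.EdgeWeightParams(
            epsilon=self.harmonic.epsilon,
            concave_angle_tol=self.harmonic.concave_tol_rad,
            gamma_mode=self.harmonic.gamma_mode,
            sigma=self.harmonic.sigma,
        )


# ----------------------------------------------------------------------
@dataclass
class PipelineOutput:
    """Everything the pipeline computed, plus the machine-readable report."""

    segmentation: _boundary.SegmentationResult
    clipped_mesh: TriangleMesh
    cut: _gingiva.CutPlaneResult
    groups: _features.FeaturePointGroups
    field: _harmonic.HarmonicField
    report: dict


def segment_mesh(
    mesh: TriangleMesh,
    feature_points: np.ndarray,
    occlusal: Plane,
    config: PipelineConfig | None = None,
) -> PipelineOutput:
    """Run the full segmentation on in-memory inputs.

    ``feature_points`` are raw cusp/incisal coordinates (mm); they are
    snapped to the mesh, grouped per tooth along the fitted arch, and
    used as the alternating 0/1 constraints.
    """
    cfg = config or PipelineConfig()
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    features = _features.snap_to_mesh(feature_points, mesh)
    if np.mean(occlusal.signed_distance(features.points)) < 0:
        occlusal = Plane(occlusal.origin, -occlusal.normal)
    arch = _features.fit_arch(features, occlusal)
    groups = _features.group_by_spokes(
        features, arch, gap_threshold=cfg.features.gap_threshold_mm
    )
    timings["features"] = time.perf_counter() - t0
    log.info("feature grouping: %d points -> %d tooth groups", len(features), groups.n_groups)

    t0 = time.perf_counter()
    curvature_full = principal_curvatures(mesh, ring_radius=cfg.curvature.ring_radius)
    cut = _gingiva.cut_gingiva(
        mesh,
        occlusal,
        curvature_full,
        d=cfg.sweep.step_mm,
        min_loop_points=cfg.sweep.min_loop_points,
        threshold=cfg.sweep.energy_threshold,
    )
    clipped = cut.clipped_mesh
    timings["gingiva_cut"] = time.perf_counter() - t0
    log.info(
        "gingiva cut at sweep step %d (%d -> %d faces)",
        cut.selected_step.index, mesh.n_faces, clipped.n_faces,
    )

    t0 = time.perf_counter()
    # feature vertices carry over to the clipped mesh by position
    clipped_features = _features.snap_to_mesh(features.points, clipped)
    clipped_groups = _features.group_by_spokes(
        clipped_features, arch, gap_threshold=cfg.features.gap_threshold_mm
    )
    params = cfg.weight_params()
    field = _harmonic.solve_dental_field(
        clipped,
        clipped_groups.omega1,
        clipped_groups.omega2,
        cut.omega3,
        params=params,
        w=cfg.harmonic.w,
    )
    timings["harmonic_field"] = time.perf_counter() - t0
    log.info("harmonic field solved, residual %.3g", field.residual)

    t0 = time.perf_counter()
    curvature_clipped = principal_curvatures(
        clipped, ring_radius=cfg.curvature.ring_radius
    )
    boundaries, flagged = _boundary.select_boundaries(
        clipped, field, clipped_groups, curvature_clipped,
        n_levels=cfg.boundary.n_levels,
    )
    segmentation = _boundary.label_faces(clipped, boundaries, clipped_groups)
    segmentation.flagged = flagged
    timings["boundary_extraction"] = time.perf_counter() - t0
    log.info("boundaries: %d teeth, %d flagged", len(boundaries), len(flagged))

    report = {
        "teeth_found": len(boundaries),
        "flagged_teeth": flagged,
        "groups": groups.n_groups,
        "cut_step": int(cut.selected_step.index),
        "boundary_lengths_mm": {
            str(k): round(lp.length, 6) for k, lp in boundaries.items()
        },
        "faces": int(clipped.n_faces),
        "vertices": int(clipped.n_vertices),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    return PipelineOutput(
        segmentation=segmentation,
        clipped_mesh=clipped,
        cut=cut,
        groups=clipped_groups,
        field=field,
        report=report,
    )


def run_pipeline(config: PipelineConfig) -> PipelineOutput:
    """File-based pipeline entry: reads inputs, writes all outputs."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    mesh = load_mesh(config.mesh_path)
    raw_features, occlusal = _features.load_features(config.features_path, mesh)
    out = segment_mesh(mesh, raw_features.points, occlusal, config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    export_result(out, outdir)
    return out


def export_result(out: PipelineOutput, outdir: Path) -> None:
    """Write labels, boundaries, diagnostics, and the report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seg = out.segmentation
    # per-face labels, one per line
    np.savetxt(outdir / "labels.txt", seg.labels, fmt="%d")
    for tooth_id, lp in seg.boundaries.items():
        np.savetxt(
            outdir / f"boundary_{tooth_id:02d}.xyz", lp.points, fmt="%.6f"
        )
    (outdir / "sweep.csv").write_text(_gingiva.sweep_diagnostics_csv(out.cut.steps))
    (outdir / "report.json").write_text(json.dumps(out.report, indent=2) + "\n")
    out.clipped_mesh.save(outdir / "clipped.ply")


# ----------------------------------------------------------------------
# evaluation
def resample_polyline(points: np.ndarray, spacing: float = 0.05,
                      closed: bool = True) -> np.ndarray:
    """Evenly spaced samples along a polyline (mm)."""
    p = np.asarray(points, dtype=float)
    if closed:
        p = np.vstack([p, p[:1]])
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return p[:1]
    targets = np.arange(0.0, total, spacing)
    idx = np.searchsorted(s, targets, side="right") - 1
    idx = np.clip(idx, 0, len(seg) - 1)
    frac = (targets - s[idx]) / np.where(seg[idx] == 0, 1.0, seg[idx])
    return p[idx] + frac[:, None] * (p[idx + 1] - p[idx])


def symmetric_polyline_distance(a: np.ndarray, b: np.ndarray,
                                spacing: float = 0.05) -> float:
    """Mean symmetric closest-point distance between two polylines (mm)."""
    pa = resample_polyline(a, spacing)
    pb = resample_polyline(b, spacing)
    d_ab, _ = cKDTree(pb).query(pa)
    d_ba, _ = cKDTree(pa).query(pb)
    return float(0.5 * (d_ab.mean() + d_ba.mean()))


def evaluate(out: PipelineOutput, truth) -> dict:
    """Compare a segmentation with arch-fixture ground truth.

    Returns per-tooth mean symmetric boundary distances (mm), the
    per-face label agreement fraction on the clipped mesh, and the ids of
    unsegmented (excluded) teeth.  Tooth correspondence is established by
    nearest ground-truth apex to each group's feature points.
    """
    clipped = out.clipped_mesh
    seg = out.segmentation
    truth_ids = sorted(truth.apices)
    apex_pts = np.array([truth.apices[t] for t in truth_ids])
    apex_tree = cKDTree(apex_pts)

    mapping: dict[int, int] = {}  # result tooth id -> truth tooth id
    for gi, g in enumerate(out.groups.groups):
        d, j = apex_tree.query(g.points)
        d = np.atleast_1d(d)
        j = np.atleast_1d(j)
        best = j[np.argmin(d)]
        if np.min(d) > 2.0 * _features.SNAP_TOL_MM + 2.0:
            raise EvaluationError(
                f"group {gi} features match no ground-truth apex (distance {np.min(d):.2f} mm)"
            )
        mapping[gi + 1] = truth_ids[int(best)]
    if len(set(mapping.values())) != len(mapping):
        raise EvaluationError("two feature groups map to the same ground-truth tooth")

    per_tooth: dict[int, float] = {}
    for tooth_id, lp in seg.boundaries.items():
        gt = truth.boundaries[mapping[tooth_id]]
        per_tooth[tooth_id] = symmetric_polyline_distance(lp.points, gt)
    excluded = list(seg.flagged)

    centroids = clipped.vertices[clipped.faces].mean(axis=1)
    gt_labels = truth.label_points(centroids)
    remap = np.zeros(max(mapping, default=0) + 1, dtype=np.int64)
    for rid, tid in mapping.items():
        remap[rid] = tid
    pred = remap[seg.labels]
    agreement = float(np.mean(pred == gt_labels))

    mean_err = float(np.mean(list(per_tooth.values()))) if per_tooth else float("nan")
    return {
        "per_tooth_boundary_error_mm": per_tooth,
        "mean_boundary_error_mm": mean_err,
        "label_agreement": agreement,
        "excluded_teeth": excluded,
        "tooth_mapping": mapping,
    }


def evaluate_exported(clipped_mesh: TriangleMesh, labels: np.ndarray,
                      boundaries: dict, truth) -> dict:
    """Evaluate an exported segmentation (files) against fixture truth.

    ``boundaries`` maps tooth id -> (k, 3) polyline array.  Result teeth
    are matched to ground-truth teeth by closest boundary centroid.
    """
    if len(labels) != clipped_mesh.n_faces:
        raise EvaluationError(
            f"label count {len(labels)} does not match mesh faces {clipped_mesh.n_faces}"
        )
    truth_ids = sorted(truth.boundaries)
    gt_centroids = np.array([truth.boundaries[t].mean(axis=0) for t in truth_ids])
    mapping: dict[int, int] = {}
    for tid, poly in boundaries.items():
        d = np.linalg.norm(gt_centroids - np.asarray(poly).mean(axis=0), axis=1)
        mapping[tid] = truth_ids[int(np.argmin(d))]
    if len(set(mapping.values())) != len(mapping):
        raise EvaluationError("two result boundaries map to the same ground-truth tooth")
    per_tooth = {
        tid: symmetric_polyline_distance(np.asarray(poly), truth.boundaries[mapping[tid]])
        for tid, poly in boundaries.items()
    }
    centroids = clipped_mesh.vertices[clipped_mesh.faces].mean(axis=1)
    gt_labels = truth.label_points(centroids)
    remap = np.zeros(max(mapping, default=0) + 1, dtype=np.int64)
    for rid, t in mapping.items():
        remap[rid] = t
    agreement = float(np.mean(remap[labels] == gt_labels))
    mean_err = float(np.mean(list(per_tooth.values()))) if per_tooth else float("nan")
    return {
        "per_tooth_boundary_error_mm": per_tooth,
        "mean_boundary_error_mm": mean_err,
        "label_agreement": agreement,
        "excluded_teeth": sorted(set(range(1, truth.n_teeth + 1)) - set(mapping.values())),
        "tooth_mapping": mapping,
    }
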