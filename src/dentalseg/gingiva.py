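"""Automatic gingiva cutting by a curvature-variance plane sweep.

A plane starts at the occlusal plane and moves toward the model base in
steps of ``d`` mm.  Steps whose intersection with the surface is a single
closed-ish loop are scored by the sample variance of the minimum
principal curvature along the loop,

    φ = 1/(n-1) Σ (c_min,k − c_min,avg)²,

which is high while the loop still grazes tooth anatomy and settles low
on smooth gum.  After the sweep the one-loop energies are min-max
normalized to [0, 1]; scanning in sweep order, the cutting plane is the
last step of the first maximal strictly-decreasing run of normalized
energies below 0.5.  If the sweep exits the mesh before such a stop, the
last one-loop plane is used.  The model below the chosen plane is clipped
away and the cut-loop vertices (Ω3) are recorded as the 0.5 Dirichlet
constraints of the harmonic field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CutSelectionError, ParameterError, UndefinedEnergyError
from .mesh import (
    CurvatureField,
    IntersectionLoop,
    Plane,
    TriangleMesh,
    clip_below_plane,
    intersect_with_plane,
)

DEFAULT_STEP_MM = 1.0
DEFAULT_MIN_LOOP_POINTS = 8
ENERGY_THRESHOLD = 0.5


@dataclass
class SweepStep:
    """One position of the moving cut plane."""

    index: int  # i >= 1; origin = occlusal origin - i*d*normal
    plane: Plane
    loops: list
    phi: float | None = None  # variance energy; defined iff one meaningful loop
    phi_normalized: float | None = None

    @property
    def one_loop(self) -> bool:
        return self.phi is not None


@dataclass
class CutPlaneResult:
    steps: list
    selected: int  # index into ``steps`` of the chosen plane
    omega3: np.ndarray  # cut-loop vertex ids of the clipped mesh
    clipped_mesh: TriangleMesh

    @property
    def selected_step(self) -> SweepStep:
        return self.steps[self.selected]


def variance_energy(kmin_samples: np.ndarray) -> float:
    """Sample variance (1/(n-1) normalization) of curvature samples."""
    k = np.asarray(kmin_samples, dtype=float).ravel()
    n = len(k)
    if n < 2:
        raise UndefinedEnergyError(f"variance energy needs >= 2 samples, got {n}")
    avg = k.mean()
    return float(np.sum((k - avg) ** 2) / (n - 1))


def sample_kmin_on_loop(loop: IntersectionLoop, curvature: CurvatureField) -> np.ndarray:
    """k_min at loop points, linearly interpolated along the crossed edges."""
    k = curvature.k_min
    out = np.empty(len(loop.edge_refs))
    for i, ((a, b), t) in enumerate(loop.edge_refs):
        out[i] = (1.0 - t) * k[a] + t * k[b]
    return out


def sweep(
    mesh: TriangleMesh,
    occlusal: Plane,
    d: float,
    curvature: CurvatureField,
    min_loop_points: int = DEFAULT_MIN_LOOP_POINTS,
    max_steps: int = 10000,
) -> list[SweepStep]:
    """Move the plane down from the occlusal plane until it exits the mesh.

    Loops shorter than ``min_loop_points`` are treated as non-meaningful
    (tangential grazing) and ignored for the one-loop test.
    """
    if d <= 0:
        raise ParameterError(f"sweep step must be positive, got {d}")
    steps: list[SweepStep] = []
    # sweep only while the plane can still meet the mesh
    min_height = float(occlusal.signed_distance(mesh.vertices).min())
    for i in range(1, max_steps + 1):
        plane = occlusal.offset(-i * d)
        if -i * d < min_height:
            break
        loops = intersect_with_plane(mesh, plane)
        step = SweepStep(index=i, plane=plane, loops=loops)
        meaningful = [lp for lp in loops if len(lp) >= min_loop_points]
        if len(meaningful) == 1:
            samples = sample_kmin_on_loop(meaningful[0], curvature)
            if len(samples) >= 2:
                step.phi = variance_energy(samples)
        steps.append(step)
    _normalize_energies(steps)
    return steps


def _normalize_energies(steps: list[SweepStep]) -> None:
    """Min-max map the one-loop energies onto [0, 1], in place."""
    phis = np.array([s.phi for s in steps if s.one_loop], dtype=float)
    if len(phis) == 0:
        return
    lo, hi = phis.min(), phis.max()
    span = hi - lo
    for s in steps:
        if s.one_loop:
            s.phi_normalized = float((s.phi - lo) / span) if span > 0 else 0.0


def select_cut_step(steps: list[SweepStep],
                    threshold: float = ENERGY_THRESHOLD) -> int:
    """Index (into ``steps``) of the selected cutting plane.

    Scans one-loop steps in sweep order for the first maximal strictly
    decreasing run of normalized energies below ``threshold`` and returns
    its last step; falls back to the last one-loop plane when the sweep
    exits the mesh while still decreasing (or never drops below the
    threshold).
    """
    one_loop = [(i, s) for i, s in enumerate(steps) if s.one_loop]
    if not one_loop:
        raise CutSelectionError("no one-loop sweep step to select a cutting plane from")
    run_last = None
    prev_val = None
    for i, s in one_loop:
        val = s.phi_normalized
        if run_last is None:
            if val < threshold:
                run_last, prev_val = i, val
        else:
            if val < prev_val:  # still strictly decreasing (ties stop the run)
                run_last, prev_val = i, val
            else:
                return run_last
    # sweep exited the mesh first: use the last one-loop plane
    return one_loop[-1][0]


def cut_gingiva(
    mesh: TriangleMesh,
    occlusal: Plane,
    curvature: CurvatureField,
    d: float = DEFAULT_STEP_MM,
    min_loop_points: int = DEFAULT_MIN_LOOP_POINTS,
    threshold: float = ENERGY_THRESHOLD,
) -> CutPlaneResult:
    """Sweep, select the gingiva cutting plane, and clip the model."""
    steps = sweep(mesh, occlusal, d, curvature, min_loop_points=min_loop_points)
    selected = select_cut_step(steps, threshold=threshold)
    clipped, omega3 = clip_below_plane(mesh, steps[selected].plane)
    return CutPlaneResult(
        steps=steps, selected=selected, omega3=omega3, clipped_mesh=clipped
    )


def sweep_diagnostics_csv(steps: list[SweepStep]) -> str:
    """Per-step CSV dump: index, loop_count, phi, phi_normalized."""
    lines = ["index,loop_count,phi,phi_normalized"]
    for s in steps:
        phi = "" if s.phi is None else f"{s.phi:.9g}"
        phin = "" if s.phi_normalized is None else f"{s.phi_normalized:.9g}"
        lines.append(f"{s.index},{len(s.loops)},{phi},{phin}")
    return "\n".join(lines) + "\n"
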