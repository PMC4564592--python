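"""Exception hierarchy for the segmentation pipeline.

Every stage raises a subclass of :class:`DentalSegError` so the CLI can
abort with the stage name and a nonzero exit status.
"""


class DentalSegError(Exception):
    """Base class for all package errors."""


class MeshFormatError(DentalSegError):
    """A mesh file could not be parsed as the named format."""


class MeshValidationError(DentalSegError):
    """Mesh violates manifoldness / nondegeneracy invariants."""


class EdgeLookupError(DentalSegError):
    """Requested edge is not part of the mesh."""


class UndefinedDihedralError(DentalSegError):
    """Dihedral angle requested for a boundary edge."""


class ClipError(DentalSegError):
    """Plane clipping precondition violated (no intersection)."""


class SnapError(DentalSegError):
    """Feature point too far from the mesh surface to snap."""


class FeatureFormatError(DentalSegError):
    """Feature sidecar file malformed or missing the occlusal plane."""


class ArchFitError(DentalSegError):
    """Dental-arch curve fit is rank deficient or underdetermined."""


class ParameterError(DentalSegError):
    """Invalid numeric parameter (e.g. nonpositive sweep step)."""


class UndefinedEnergyError(DentalSegError):
    """Variance energy requested for fewer than two samples."""


class CutSelectionError(DentalSegError):
    """No one-loop sweep step available to select a cutting plane."""


class ConstraintConflictError(DentalSegError):
    """A vertex appears in more than one Dirichlet constraint set."""


class SolverError(DentalSegError):
    """Sparse factorization failed (singular system)."""


class ScoringError(DentalSegError):
    """Loop score requested for an open polyline."""


class BoundaryTopologyError(DentalSegError):
    """Tooth boundary loops cross each other."""


class FixtureSpecError(DentalSegError):
    """Synthetic fixture specification is inconsistent."""


class EvaluationError(DentalSegError):
    """Segmentation result and ground truth refer to different meshes."""


class ConfigError(DentalSegError):
    """Pipeline configuration failed schema validation."""
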