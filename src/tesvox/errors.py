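"""Exception hierarchy shared across the pipeline stages."""


class TesvoxError(Exception):
    """Base class for all tesvox errors."""


class VolumeFormatError(TesvoxError):
    """Input file is not a volume this package can consume."""


class VocabularyError(TesvoxError):
    """A labeled volume contains labels outside the canonical vocabulary."""


class ConfigurationError(TesvoxError):
    """Invalid user configuration (tissue names, conductivities, ...)."""


class AlignmentError(TesvoxError):
    """Two volumes expected on the same grid are not."""


class PlacementError(TesvoxError):
    """Electrode or fiducial placement failed."""


class CollisionError(PlacementError):
    """An electrode would overlap a previously placed electrode or gel."""


class BoundaryConditionError(TesvoxError):
    """Current boundary conditions cannot be applied (e.g. buried electrode)."""


class SolverError(TesvoxError):
    """The linear solver failed to converge."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class GeometryError(TesvoxError):
    """A phantom specification does not fit its grid."""


class RecipeError(TesvoxError):
    """A montage recipe string failed to parse."""


class UndefinedStatisticError(TesvoxError):
    """A requested statistic is undefined for the given data."""


class EvaluationError(TesvoxError):
    """Analytic oracle evaluated at an invalid point."""
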