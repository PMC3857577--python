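"""Exception hierarchy shared across the package."""


class LesionLoadError(Exception):
    """Base class for all package-specific errors."""


class VolumeIOError(LesionLoadError, IOError):
    """A volume file could not be read or written."""


class DimensionalityError(LesionLoadError, ValueError):
    """A volume does not have the expected number of spatial dimensions."""


class GridMismatchError(LesionLoadError, ValueError):
    """Two volumes do not share the same voxel grid (shape + affine)."""


class EmptyMapError(LesionLoadError, ValueError):
    """An operation requires at least one nonzero voxel."""


class SchemaError(LesionLoadError, ValueError):
    """A cohort table is missing required columns or contains bad cells."""


class SingularDesignError(LesionLoadError, ValueError):
    """A regression design matrix is rank deficient."""


class SampleSizeError(LesionLoadError, ValueError):
    """Too few usable records to fit a model."""


class DegenerateInputError(LesionLoadError, ValueError):
    """Input has no variation (e.g. all scores equal) where variation is required."""


class GeometryError(LesionLoadError, ValueError):
    """A synthetic shape cannot be realised inside the requested grid."""
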