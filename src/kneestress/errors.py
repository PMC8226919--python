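"""Exception hierarchy shared by the pipeline stages."""


class KneeStressError(Exception):
    """Base class for all pipeline errors."""


class MetadataError(KneeStressError):
    """Invalid or contradictory volume metadata (spacing, axis semantics)."""


class ConfigurationError(KneeStressError):
    """Unknown ACL condition / loading configuration label or bad config value."""


class FieldOfViewError(KneeStressError):
    """A phantom solid does not fit inside the volume bounds."""


class InsufficientMaskError(KneeStressError):
    """Too few labeled voxels to estimate bone geometry."""


class AxisUndefinedError(KneeStressError):
    """Near-isotropic voxel cloud: no principal elongation to define an axis."""


class NoIntersectionError(KneeStressError):
    """The central axis does not exit the bone mask toward the joint."""


class AnnotationError(KneeStressError):
    """Missing or malformed landmark/axis annotation."""


class MissingStructureError(KneeStressError):
    """A label required by a 2D measure is absent from the selected slice."""


class GeometryError(KneeStressError):
    """Degenerate geometric input (e.g. zero-length direction)."""


class DesignError(KneeStressError):
    """Incomplete repeated-measures design (missing study cell)."""


class DegenerateDataError(KneeStressError):
    """Zero-variance or otherwise degenerate data for a statistical routine."""


class DataError(KneeStressError):
    """Not enough observations for a statistical routine."""


class ParameterError(KneeStressError):
    """Statistical parameter out of range or target unreachable."""
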