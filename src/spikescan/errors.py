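"""Exception hierarchy shared across the package."""


class SpikeScanError(Exception):
    """Base class for all spikescan errors."""


class ValidationError(SpikeScanError, ValueError):
    """A parameter or input value violates its contract."""


class SizingError(SpikeScanError):
    """A requested canvas or geometry does not fit the allowed bounds."""


class EmptySceneError(SpikeScanError):
    """No foreground object was found in the image."""


class GeometryError(SpikeScanError):
    """A geometric computation is degenerate (e.g. zero-variance body)."""


class CalibrationError(SpikeScanError):
    """Scale or color calibration could not be established."""


class FormatError(SpikeScanError, ValueError):
    """A file does not conform to the expected on-disk format."""


class DimensionError(SpikeScanError):
    """Paired rasters have mismatching dimensions."""


class ReferentialError(SpikeScanError):
    """A database row refers to a missing parent record."""


class MigrationError(SpikeScanError):
    """An existing database file has an incompatible schema."""


class DuplicateViewError(ValidationError):
    """Two view records carry the same view label for one spike."""


class FramingWarning(UserWarning):
    """The foreground touches three or more image borders."""
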