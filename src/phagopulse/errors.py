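"""Exception hierarchy.

All package errors derive from :class:`PhagopulseError` so callers can catch
one base class; specific subclasses mirror failure modes of the pipeline
stages (configuration, generation, file format, calibration, array shape,
processing-state violations).
"""


class PhagopulseError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PhagopulseError, ValueError):
    """Invalid parameter value or inconsistent configuration."""


class GenerationError(PhagopulseError, RuntimeError):
    """Synthetic-movie generation failed (e.g. object exceeds image bounds)."""


class FormatError(PhagopulseError, ValueError):
    """File or in-memory layout does not match the expected format."""


class CalibrationError(PhagopulseError, ValueError):
    """Physical calibration (voxel size / frame interval) missing or invalid."""


class ShapeError(PhagopulseError, ValueError):
    """Array geometries that must match do not."""


class StateError(PhagopulseError, ValueError):
    """Input is in the wrong processing state (e.g. unnormalized trace)."""


class DegenerateGeometryError(PhagopulseError, ValueError):
    """A geometric construction produced an empty result (e.g. empty ring)."""
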