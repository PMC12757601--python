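"""Exception hierarchy shared across the package."""


class PSFDecoupleError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PSFDecoupleError, ValueError):
    """Invalid parameter value or inconsistent input arrays."""


class EmptyApertureError(ValidationError):
    """A pupil mask that blocks the entire aperture."""


class PlacementError(PSFDecoupleError, RuntimeError):
    """Phantom objects cannot be placed under the requested constraints."""


class ExtractionError(PSFDecoupleError, RuntimeError):
    """Bead-based PSF extraction retained no usable beads."""


class FormatError(PSFDecoupleError, ValueError):
    """Unsupported image file layout or sample format."""


class ConfigurationError(PSFDecoupleError, ValueError):
    """Required configuration (e.g. voxel sizes) is missing."""
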