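"""Exception hierarchy.

All package errors derive from :class:`MprheoError` so callers (and the CLI)
can map failures to exit codes: data/format problems vs. numerical/calibration
failures.
"""


class MprheoError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(MprheoError, ValueError):
    """A physical or configuration parameter is out of its valid domain."""


class FormatError(MprheoError, ValueError):
    """An input file or array does not have the expected structure."""


class OutOfBoundsError(MprheoError, ValueError):
    """A bead position falls outside the renderable sub-image area."""


class DegenerateImageError(MprheoError, ValueError):
    """An image is constant or all-zero where structure is required."""


class NoObjectError(MprheoError, ValueError):
    """Thresholding left no foreground pixels to localise."""


class InsufficientRangeError(MprheoError, ValueError):
    """Calibration data do not span enough distinct sharpest-plane steps."""


class CalibrationError(MprheoError, RuntimeError):
    """The rescaling calibration fit failed (e.g. non-positive gradient)."""


class InsufficientScanError(MprheoError, ValueError):
    """A z-scan covers too few planes to characterise the plane spacing."""


class TrajectoryTooShortError(MprheoError, ValueError):
    """A trajectory is too short for the requested correlation analysis."""
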