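"""Typed exceptions raised across the package."""


class LofdetectError(Exception):
    """Base class for all package errors."""


class ParameterError(LofdetectError, ValueError):
    """An argument is out of its valid range or inconsistent with the data."""


class DegenerateDimensionError(ParameterError):
    """A standardized-euclidean scale entry is zero (constant coordinate)."""

    def __init__(self, dimensions):
        self.dimensions = list(dimensions)
        shown = self.dimensions[:10]
        more = "" if len(self.dimensions) <= 10 else f" (+{len(self.dimensions) - 10} more)"
        super().__init__(
            "standardized-euclidean scale is zero for sample dimension(s) "
            f"{shown}{more}; these coordinates are constant across channels"
        )


class InsufficientChannelsError(ParameterError):
    """Fewer channels available than the operation requires."""


class CalibrationDegenerateError(LofdetectError, ValueError):
    """Calibration cannot proceed (e.g. no bad channels in the training set)."""


class SplitInfeasibleError(LofdetectError, ValueError):
    """Requested cross-validation split cannot be constructed."""


class AnnotationError(LofdetectError, ValueError):
    """A bad-channel annotation refers to an unknown channel."""


class RecordingIOError(LofdetectError, OSError):
    """A recording file is missing, malformed, or in an unknown format."""


class LowDensityWarning(UserWarning):
    """The montage has fewer channels than the method is recommended for."""


class DegenerateGeometryWarning(UserWarning):
    """All channels are (numerically) identical; neighborhood size is arbitrary."""
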