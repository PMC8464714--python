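"""Exception hierarchy for epidose.

All package errors derive from :class:`EpidoseError` so callers can catch
one base class; the subclasses mirror the failure modes of the pipeline
stages (I/O, geometry, calibration data, fitting, gamma analysis).
"""


class EpidoseError(Exception):
    """Base class for all epidose errors."""


class FormatError(EpidoseError):
    """Malformed or unsupported on-disk data (bad CSV, truncated JSON, ...)."""


class MetadataError(FormatError):
    """Required geometry metadata missing and defaults disabled."""


class GeometryError(EpidoseError):
    """Incompatible or out-of-extent detector geometry."""


class ConfigurationError(EpidoseError):
    """Invalid pipeline/calibration configuration (missing matrix class, ...)."""


class CalibrationDataError(EpidoseError):
    """Measured calibration data violates a precondition (zero pixel in mask, ...)."""


class FloodFieldError(EpidoseError):
    """Flood-field correction impossible: FF - DF non-positive somewhere."""

    def __init__(self, n_bad: int):
        self.n_bad = n_bad
        super().__init__(
            f"flood-field correction undefined: FF - DF <= 0 at {n_bad} pixel(s)"
        )


class FitError(EpidoseError):
    """Dose-conversion fit impossible (too few MU levels, degenerate data)."""


class AnalysisError(EpidoseError):
    """Gamma analysis cannot be performed (empty evaluated region, ...)."""
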