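"""Exception and warning types shared across the package."""


class TransitDoseError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(TransitDoseError, ValueError):
    """A source/detector/plane distance or setup parameter is unphysical."""


class DegenerateApertureError(TransitDoseError, ValueError):
    """Aperture has no open area."""


class OutOfRangeError(TransitDoseError, ValueError):
    """A depth or coordinate lies outside the phantom or grid."""


class InvalidInputError(TransitDoseError, ValueError):
    """Generic contract violation on an operation input."""


class InsufficientDataError(TransitDoseError, ValueError):
    """Too few records to perform a fit or extrapolation."""


class InvalidCalibrationError(TransitDoseError, ValueError):
    """Calibration data are inconsistent, non-monotone or incomplete."""


class InvalidReferenceError(TransitDoseError, ValueError):
    """Reference profile/plane has a non-positive normalization dose."""


class GridMismatchError(TransitDoseError, ValueError):
    """Two planes do not share spacing/origin/shape where required."""


class CoverageError(TransitDoseError, ValueError):
    """Truth plane does not cover the detector footprint."""


class IncompleteFillerError(TransitDoseError, ValueError):
    """Filler plane is missing a value needed to complete a sampled plane."""


class OpenFieldEdgeError(TransitDoseError, ValueError):
    """Profile never falls below 50% of its central-axis dose."""


class FitFailureError(TransitDoseError, RuntimeError):
    """Optimizer failed to converge; carries diagnostics in args."""


class TruncationWarning(UserWarning):
    """Realized kernel grid captures less than 99.9% of the analytic mass."""


class ExtrapolationWarning(UserWarning):
    """A lookup/evaluation was requested outside the calibrated domain."""
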