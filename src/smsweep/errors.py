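"""Exception types shared across the package."""


class SmSweepError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(SmSweepError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(SmSweepError):
    """Not enough data points / pairs / dwells to perform the operation."""


class FitFailureError(SmSweepError):
    """A nonlinear fit did not converge; message carries diagnostics."""


class CalibrationError(SmSweepError):
    """Bead calibration residuals exceed tolerance or inputs are unusable."""
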