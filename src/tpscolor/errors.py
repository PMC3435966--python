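"""Exception hierarchy for calibration failures.

Every error carries enough context (patch id, file, row) for the CLI to
report a categorized, actionable message and a nonzero exit status.
"""


class CalibrationError(Exception):
    """Base class for all errors raised by this package."""

    category = "error"


class InvalidInputError(CalibrationError):
    """A value violates a documented precondition (range, shape, sign)."""

    category = "invalid-input"


class FormatError(CalibrationError):
    """A file could not be parsed; the message names the offending row."""

    category = "format"


class SingularSystemError(CalibrationError):
    """The interpolation system is singular or numerically ill-conditioned,
    usually because two control patches measured (near-)identical colors."""

    category = "singular-system"


class PairingError(CalibrationError):
    """Measured patch ids could not be matched to the reference chart."""

    category = "pairing"


class BoundsError(CalibrationError):
    """A layout region falls outside the image."""

    category = "bounds"
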