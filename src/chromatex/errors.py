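"""Exception hierarchy with stable machine-readable codes.

Every failure mode of the pipeline carries a short upper-case ``code``
so batch drivers and the CLI can log and classify failures without
string-matching messages.
"""

from __future__ import annotations


class ChromatexError(ValueError):
    """Base class for all validation/processing errors raised by this package."""

    code: str = "ERROR"

    def __init__(self, message: str = ""):
        super().__init__(f"{self.code}: {message}" if message else self.code)


class EmptyStackError(ChromatexError):
    code = "EMPTY_STACK"


class BadRadiusError(ChromatexError):
    code = "BAD_RADIUS"


class NoObjectError(ChromatexError):
    code = "NO_OBJECT"


class ShapeMismatchError(ChromatexError):
    code = "SHAPE_MISMATCH"


class BadKernelError(ChromatexError):
    code = "BAD_KERNEL"


class NoPairsError(ChromatexError):
    code = "NO_PAIRS"


class NoValidWindowsError(ChromatexError):
    code = "NO_VALID_WINDOWS"


class EmptySampleError(ChromatexError):
    code = "EMPTY_SAMPLE"


class TooFewSamplesError(ChromatexError):
    code = "TOO_FEW_SAMPLES"


class EmptyCohortError(ChromatexError):
    code = "EMPTY_COHORT"


class BadKError(ChromatexError):
    code = "BAD_K"


class DegenerateAxisError(ChromatexError):
    code = "DEGENERATE_AXIS"


class ZeroCountsError(ChromatexError):
    code = "ZERO_COUNTS"


class ZeroAcceptorError(ChromatexError):
    code = "ZERO_ACCEPTOR"


class TooFewConditionsError(ChromatexError):
    code = "TOO_FEW_CONDITIONS"


class BadSpecError(ChromatexError):
    code = "BAD_SPEC"


class MissingCalibrationError(ChromatexError):
    code = "MISSING_CALIBRATION"


class EmptyInputError(ChromatexError):
    code = "EMPTY_INPUT"


class DegenerateMarginWarning(UserWarning):
    """Training cohorts are not separable in any meaningful sense."""
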