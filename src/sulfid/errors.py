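"""Exception hierarchy for the pipeline.

Every error raised on a user-facing path derives from SulfidError so the
CLI can map failures to stable exit codes.
"""

from __future__ import annotations


class SulfidError(Exception):
    """Base class for all package errors."""


class FormatError(SulfidError):
    """A file could not be parsed in the declared dialect."""


class ValidationError(SulfidError):
    """An input value or data structure violates an invariant."""


class DomainError(SulfidError):
    """A numeric argument lies outside the mathematically admissible domain."""


class RatioRangeError(DomainError):
    """An isotope ratio falls outside the open interval bounded by the
    spike and sample isotope ratios; carries which bound was violated."""

    def __init__(self, message: str, bound: str):
        super().__init__(message)
        self.bound = bound  # "spike" or "sample"


class ContractError(SulfidError):
    """An operation was called in a state its contract forbids
    (e.g. double mass-bias correction)."""


class DegenerateTraceError(SulfidError):
    """Every point of a trace was masked; no ratio can be formed."""


class InsufficientDataError(SulfidError):
    """Too few points or replicates to perform the requested operation."""


class BlankEstimationError(SulfidError):
    """The declared blank regions contain no trace points."""


class CalibrationError(SulfidError):
    """The calibration design is unusable (too few levels, zero variance)."""


class PropagationError(SulfidError):
    """The measurement model failed to evaluate at a perturbed point."""

    def __init__(self, message: str, input_name: str | None = None):
        super().__init__(message)
        self.input_name = input_name
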