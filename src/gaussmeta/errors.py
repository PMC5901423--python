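"""Exception hierarchy for gaussmeta.

Every contract violation raises a distinct, named error so callers (and the
CLI) can map failures to exit codes.
"""


class GaussMetaError(Exception):
    """Base class for all gaussmeta errors."""


class MissingColumnError(GaussMetaError):
    """A required column is absent from an input table."""


class EmptyDataError(GaussMetaError):
    """An input table contains no usable rows."""


class TreatmentCodingError(GaussMetaError):
    """The treatment column does not have exactly two levels."""


class StudyValidationError(GaussMetaError):
    """A study violates a structural invariant (e.g. a missing arm)."""


class DegenerateStudyError(GaussMetaError):
    """A study contributes a degenerate quantity (zero variance, zero df)."""


class MissingArmSizesError(GaussMetaError):
    """Arm sizes are required for the requested method but unavailable."""


class UnsupportedModelError(GaussMetaError):
    """The requested model / variance-assumption combination is not defined."""


class UnsupportedFormulaError(GaussMetaError):
    """No closed-form expectation exists for the requested formula."""


class ConvergenceError(GaussMetaError):
    """An iterative fit failed to converge; carries the optimizer trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace
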