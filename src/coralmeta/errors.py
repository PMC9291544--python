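"""Exception hierarchy for the pipeline."""


class CoralMetaError(Exception):
    """Base class for all package errors."""


class SchemaError(CoralMetaError):
    """Input file is missing required columns or is otherwise malformed."""


class RecordValidationError(CoralMetaError):
    """One or more rows violate record invariants.

    Carries the offending row numbers (1-based, excluding the header) so the
    caller can locate them in the source file.
    """

    def __init__(self, message, rows=None):
        super().__init__(message)
        self.rows = tuple(rows) if rows is not None else ()


class DomainError(CoralMetaError):
    """A quantity is outside the mathematical domain of an operation
    (e.g. non-positive mean fed to a log ratio)."""


class DegenerateContrastError(CoralMetaError):
    """The two arms of a contrast do not differ in the driver variable
    (zero temperature or pCO2 difference)."""


class InsufficientDataError(CoralMetaError):
    """Too few effect sizes, replicates or studies for the requested fit."""


class ConvergenceError(CoralMetaError):
    """The REML optimizer failed; carries diagnostics from the profile
    evaluations tried."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics
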