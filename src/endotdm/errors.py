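"""Exception hierarchy for the endotdm package."""


class EndotdmError(Exception):
    """Base class for all endotdm errors."""


class ConfigurationError(EndotdmError):
    """A configuration document contains unknown keys or is structurally invalid."""


class ParameterValidationError(EndotdmError, ValueError):
    """A parameter value violates a model invariant.

    Carries the offending field name in :attr:`field`.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class DomainError(EndotdmError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class CoverageError(EndotdmError):
    """A life table does not cover the requested age range."""


class DataError(EndotdmError):
    """Input data are internally inconsistent (e.g. an increasing survival curve)."""


class FitError(EndotdmError):
    """A maximum-likelihood fit failed; carries diagnostics in the message."""


class UnsupportedFamilyError(EndotdmError):
    """A distribution family does not support the requested operation."""
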