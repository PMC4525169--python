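"""Exception hierarchy shared across the package."""


class PanelGwasError(Exception):
    """Base class for all package errors."""


class ParseError(PanelGwasError):
    """A file could not be parsed under the declared dialect."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ValidationError(PanelGwasError, ValueError):
    """Input values violate a documented invariant."""


class EmptyInputError(PanelGwasError):
    """No usable records remain after parsing/filtering."""


class AlignmentError(PanelGwasError):
    """Two tables that must share keys do not."""


class InsufficientDataError(PanelGwasError):
    """Too few records to carry out the requested estimate."""


class SimSpecError(PanelGwasError, ValueError):
    """A simulation specification is internally inconsistent."""


class DesignError(PanelGwasError):
    """An experimental design does not support the requested model."""
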