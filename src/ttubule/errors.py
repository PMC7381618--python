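"""Exception types shared across the package."""


class TTubuleError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(TTubuleError, ValueError):
    """An argument violates a precondition (non-positive length, etc.)."""


class DomainValidityError(TTubuleError, ValueError):
    """A model was evaluated outside its empirical domain of validity.

    Carries the offending value so callers can report which fibre size
    fell below the allometric range.
    """

    def __init__(self, message: str, value: float | None = None):
        super().__init__(message)
        self.value = value


class ROIError(TTubuleError, ValueError):
    """Hierarchy bookkeeping failure: missing parent, empty after trim, orphan."""


class QuantError(TTubuleError, ValueError):
    """Image quantification failure: empty domain, zero baseline, bad box."""
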