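"""Exception hierarchy shared across the package."""


class TwodesError(Exception):
    """Base class for all package errors."""


class DomainError(TwodesError, ValueError):
    """An argument is outside the physically or geometrically valid domain."""


class SchemaError(TwodesError, ValueError):
    """A container file or configuration document violates the published layout."""


class FitError(TwodesError, RuntimeError):
    """A fitting routine could not produce a valid result.

    Carries optional ``diagnostics`` (best-so-far parameters, SSR, iteration
    counts) so callers can inspect what the optimizer reached before failing.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
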