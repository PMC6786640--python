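"""Exception types shared across the package."""


class ProteoclockError(ValueError):
    """Base class for all package-specific errors."""


class ValidationError(ProteoclockError):
    """A domain invariant was violated (bad dataset, model, or argument)."""


class ParseError(ProteoclockError):
    """A cell or field in an input file could not be parsed."""


class ConfigurationError(ProteoclockError):
    """A layout / run configuration is inconsistent or incomplete."""
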