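"""Exception types shared across the pipeline."""


class HerbnetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HerbnetError):
    """A file does not conform to the expected tabular/GMT/CLS layout."""


class ValidationError(HerbnetError):
    """A parsed value violates a domain invariant (names the offending row)."""


class DomainError(HerbnetError, ValueError):
    """An argument violates a stated mathematical precondition."""
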