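"""Exception hierarchy shared across the package."""


class LymphriskError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(LymphriskError, ValueError):
    """An input file or config does not match the expected schema."""


class DataValidationError(LymphriskError, ValueError):
    """Structurally valid input violates a domain invariant."""


class RateLookupError(LymphriskError, KeyError):
    """A (sex, cause) combination is absent from a rate table."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0] if self.args else ""
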