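"""Exception types shared across the pipeline."""


class TotemError(Exception):
    """Base class for all package errors."""


class InvalidInputError(TotemError, ValueError):
    """Raised when an input violates a documented precondition."""


class InvalidStateError(TotemError, RuntimeError):
    """Raised when an object is used before it is fitted/valid."""


class SchemaError(TotemError, ValueError):
    """Raised when a table or model artifact does not match the expected schema."""
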