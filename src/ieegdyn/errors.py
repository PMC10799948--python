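"""Shared exception types."""


class InvalidConfigError(ValueError):
    """A configuration value violates its documented invariants."""


class UndefinedResultError(RuntimeError):
    """The requested quantity is undefined for this input (reported, never
    silently coerced to a number)."""
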