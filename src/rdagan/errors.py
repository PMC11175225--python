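"""Exception taxonomy used across the package."""


class InvalidInputError(ValueError):
    """An operation's input violates its documented preconditions."""


class InvalidStateError(RuntimeError):
    """Internal wiring mismatch (channel counts, list lengths, schema)."""


class ConfigurationError(ValueError):
    """A configuration value is outside the supported envelope."""
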