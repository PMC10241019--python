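"""Exception hierarchy shared across the package."""


class AlphaDoseError(Exception):
    """Base class for all package errors."""


class InputError(AlphaDoseError, ValueError):
    """A function argument violates its contract."""


class SchemaError(AlphaDoseError, ValueError):
    """A file does not conform to the documented column schema."""


class MappingError(AlphaDoseError, KeyError):
    """An organ (or other key) is missing from a required mapping."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return str(self.args[0]) if self.args else ""


class ConfigError(AlphaDoseError, ValueError):
    """A configuration value or scheme name is invalid."""
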