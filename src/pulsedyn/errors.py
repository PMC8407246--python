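"""Exception hierarchy shared across the pipeline."""


class PulsedynError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PulsedynError):
    """An input table does not match the expected column schema."""


class ConfigError(PulsedynError):
    """A configuration value is missing, unknown, or out of range."""


class DependencyError(PulsedynError):
    """A pipeline stage was requested before its upstream artifact exists."""
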