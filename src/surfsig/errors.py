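"""Exception types shared across the package."""


class SurfsigError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SurfsigError):
    """A configuration value is invalid; the message names the field."""


class SchemaError(SurfsigError):
    """An input table violates its schema; the message names file/line/column."""


class StageError(SurfsigError):
    """A pipeline stage failed; the message names the stage."""
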