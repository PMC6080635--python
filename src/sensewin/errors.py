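"""Exception types shared across the package."""


class SensewinError(Exception):
    """Base class for package errors."""


class ConfigError(SensewinError, ValueError):
    """A configuration value is out of range or inconsistent."""


class SchemaError(SensewinError, ValueError):
    """An input table is missing required columns or contains missing values."""
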