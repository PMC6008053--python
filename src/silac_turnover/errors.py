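"""Exception types shared across the package."""


class SilacError(Exception):
    """Base class for all package errors."""


class FormatError(SilacError):
    """A table violates the expected layout or a type invariant."""


class ConfigError(SilacError):
    """A configuration value is missing, malformed or out of range."""
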