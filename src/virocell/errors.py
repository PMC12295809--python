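"""Exception hierarchy shared across the package."""


class VirocellError(Exception):
    """Base class for package errors."""


class ConfigurationError(VirocellError):
    """A configuration value is missing, malformed or inconsistent."""


class FormatError(VirocellError):
    """An on-disk dataset violates the expected file format."""


class ValidationError(VirocellError):
    """An in-memory object violates its invariants."""
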