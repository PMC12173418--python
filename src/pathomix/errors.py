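"""Exception types shared across the package."""


class PathomixError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PathomixError):
    """An invalid configuration value; the message names the offending field."""


class ValidationError(PathomixError):
    """Invalid data passed to an operation (non-finite values, bad shapes...)."""


class FormatError(PathomixError):
    """A malformed on-disk file; the message carries the location."""
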