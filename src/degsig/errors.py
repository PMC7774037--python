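"""Exception hierarchy shared across the package."""


class DegsigError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(DegsigError):
    """An invalid configuration value; the message names the offending field."""


class ValidationError(DegsigError):
    """Data violating a documented invariant (duplicates, bad ranges, ...)."""


class ParseError(DegsigError):
    """A malformed input file; the message carries file (and line) context."""
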