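"""Exception types shared across the package."""


class KgrdrError(Exception):
    """Base class for package errors."""


class InvalidInputError(KgrdrError, ValueError):
    """Raised when user-supplied data violates an operation's contract."""


class ParseError(KgrdrError, ValueError):
    """Raised when an input file cannot be parsed."""


class ConfigError(KgrdrError, ValueError):
    """Raised for invalid or unknown configuration values."""


class ConvergenceError(KgrdrError, RuntimeError):
    """Raised when an optimization diverges irrecoverably."""
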