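"""Exception taxonomy shared across the package.

``ConfigError`` marks a bad parameter or an unresolvable configuration
(CLI exit code 2); ``DataError`` marks malformed or inconsistent input
data (CLI exit code 1).
"""


class LPIAError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(LPIAError, ValueError):
    """Invalid parameter, threshold, or configuration value."""


class DataError(LPIAError, ValueError):
    """Malformed or internally inconsistent input data."""


class ParseError(DataError):
    """A file could not be parsed; the message names the offending line."""
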