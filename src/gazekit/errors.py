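"""Exception hierarchy.

``FormatError`` — a file does not have the shape its dialect promises.
``DataError`` — the file parses but its content violates an invariant.
``ConfigError`` — a parameter is outside its documented domain.
"""


class GazekitError(Exception):
    """Base class for all package errors."""


class FormatError(GazekitError):
    """Malformed input file (wrong columns, wrong field count, ...)."""


class DataError(GazekitError):
    """Well-formed file with invalid content (non-monotonic time, gaps, ...)."""


class ConfigError(GazekitError):
    """Invalid parameter or configuration value."""
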