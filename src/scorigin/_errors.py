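"""Exception hierarchy shared across the package.

``ConfigError`` maps to CLI exit code 2, ``DataError`` (and its subclass
``FormatError``) to exit code 3.
"""


class ScoriginError(Exception):
    """Base class for all package errors."""


class ConfigError(ScoriginError):
    """Invalid configuration or parameter combination."""


class DataError(ScoriginError):
    """Input data violates a contract (shape, range, missing group...)."""


class FormatError(DataError):
    """A file on disk does not conform to the expected dialect."""
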