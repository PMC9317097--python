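"""Exception hierarchy mapped onto CLI exit codes."""


class StainCUTError(Exception):
    """Base class for package errors."""

    exit_code = 1


class ConfigurationError(StainCUTError):
    """Invalid configuration values or incompatible options."""

    exit_code = 2


class DataError(StainCUTError):
    """Unreadable, missing, or malformed input data."""

    exit_code = 3


class NumericError(StainCUTError):
    """Numerical failure (NaN/Inf in a loss or parameter update)."""

    exit_code = 4
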