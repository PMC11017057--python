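"""Exception hierarchy.

``ParameterError`` marks invalid user-supplied configuration/arguments
(CLI exit code 2); ``DataError`` marks malformed or inconsistent input
data (CLI exit code 3).
"""


class PathprsError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ParameterError(PathprsError):
    """Invalid configuration or argument values."""

    exit_code = 2


class DataError(PathprsError):
    """Malformed, inconsistent, or degenerate input data."""

    exit_code = 3
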