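"""Exception hierarchy mapped to CLI exit codes."""


class CsprsError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(CsprsError):
    """Bad user configuration: missing columns, invalid flags, unwritable paths."""

    exit_code = 2


class DataError(CsprsError):
    """Malformed or incompatible input data."""

    exit_code = 3


class NumericalError(CsprsError):
    """Numerical failure during computation (divergence, factorization failure)."""

    exit_code = 4
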