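"""Error taxonomy shared across the package and mapped to CLI exit codes."""


class VmdcalError(Exception):
    """Base class for all package-specific errors."""

    exit_code = 1


class FormatError(VmdcalError):
    """Malformed on-disk data: ragged rows, non-numeric cells, id mismatches."""

    exit_code = 2


class InvalidInputError(VmdcalError, ValueError):
    """In-memory input violates a precondition (non-finite values, shape mismatch)."""

    exit_code = 2


class ConfigError(VmdcalError, ValueError):
    """A configuration value is out of its admissible range."""

    exit_code = 3


class NumericalError(VmdcalError, ArithmeticError):
    """A numerical procedure failed (singular system, divergence)."""

    exit_code = 4
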