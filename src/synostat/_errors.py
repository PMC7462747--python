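"""Exception hierarchy shared across the package.

Distinct classes map to distinct CLI exit codes: schema errors (malformed
headers/columns), data errors (bad values in otherwise well-formed input),
config errors (invalid thresholds/parameters) and domain errors (arguments
outside a function's mathematical domain).
"""


class SynostatError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class SchemaError(SynostatError):
    """Input file lacks a required column or has a malformed header."""

    exit_code = 2


class DataError(SynostatError):
    """A value in the input violates its contract (e.g. AC > AN)."""

    exit_code = 3


class ConfigError(SynostatError):
    """Invalid configuration or parameters."""

    exit_code = 4


class DomainError(SynostatError, ValueError):
    """Argument outside the mathematical domain of an operation."""

    exit_code = 4
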