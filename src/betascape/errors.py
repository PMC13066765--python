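"""Exception hierarchy.

Exit-code mapping used by the CLI: configuration errors -> 2, data errors -> 3,
numerical failures -> 4.
"""


class BetascapeError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(BetascapeError):
    """Invalid configuration or grid/setup parameters."""

    exit_code = 2


class DomainError(BetascapeError):
    """Input values outside the mathematical domain of an operation."""

    exit_code = 3


class DataError(BetascapeError):
    """Malformed, incomplete, or inconsistent input data."""

    exit_code = 3


class DesignError(DataError):
    """Study-design violations (too few sites, empty landscapes, ...)."""


class ClassificationError(DataError):
    """Unknown or missing species classification."""


class ScreeningError(DataError):
    """Correlation screening cannot proceed (e.g. constant column)."""


class MetricError(DataError):
    """A landscape metric is undefined for the given inputs."""


class NumericalError(BetascapeError):
    """Optimisation or linear-algebra failure."""

    exit_code = 4
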