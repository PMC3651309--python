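"""Exception hierarchy.

``McsdError`` is the common base; ``InputError`` subclasses signal bad user
input (CLI exit code 2) and ``NumericalError`` subclasses signal solver or
conditioning failures (CLI exit code 3).
"""


class McsdError(Exception):
    """Base class for all package-specific errors."""


class InputError(McsdError):
    """Invalid or inconsistent user-supplied data."""


class NumericalError(McsdError):
    """A numerical procedure failed to reach its contract."""


class DuplicateIdError(InputError):
    """A probe or sample identifier occurs more than once."""


class ParseError(InputError):
    """A cell of an expression table could not be parsed as a number."""


class SampleMismatchError(InputError):
    """A requested sample is missing from one of the data blocks."""


class AlignmentError(InputError):
    """Probe identifiers/order differ between matrices that must align."""


class InsufficientSamplesError(InputError):
    """A class has too few samples for the requested statistic."""


class ConfigError(InputError):
    """A synthetic-data or run configuration violates its invariants."""


class InfeasibleError(NumericalError):
    """The equality-constrained l1 problem could not be solved to tolerance."""


class SingularCovarianceError(NumericalError):
    """The compressed-space covariance is singular beyond repair."""
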