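"""Exception hierarchy for :mod:`pepgamd`.

Every error raised deliberately by the package derives from
:class:`PepGaMDError`, so callers can catch the whole family with one
``except`` clause.  Errors that signal bad user input additionally derive
from the matching builtin (``ValueError``/``IndexError``) so that generic
handling keeps working.
"""


class PepGaMDError(Exception):
    """Base class for all pepgamd errors."""


class InvalidParameterError(PepGaMDError, ValueError):
    """A constructor or operation received an out-of-range parameter."""


class DegenerateStatisticsError(PepGaMDError):
    """Potential-energy statistics cannot support boost-parameter selection.

    Raised e.g. when ``sigma_v == 0`` or ``v_max == v_avg`` so the k0
    formulas would divide by zero.
    """


class IntegrationInstabilityError(PepGaMDError):
    """The integrator diverged (non-finite or absurdly large energy)."""

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"integration diverged at step {step}")


class InsufficientSamplesError(PepGaMDError):
    """Too few samples for the requested statistic."""


class EmptyProfileError(PepGaMDError):
    """No bin (or cluster) satisfies the frame-count cutoff."""


class InputShapeError(PepGaMDError, ValueError):
    """Mismatched lengths/shapes of paired input series."""


class NumericalOverflowError(PepGaMDError):
    """An integrand or weight is unnormalizable / non-finite."""


class TrajectoryFormatError(PepGaMDError):
    """Malformed trajectory file."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"{message} (line {line})")


class TrajectoryConsistencyError(PepGaMDError):
    """Coordinate file and energy sidecar disagree (e.g. frame counts)."""


class ConfigError(PepGaMDError):
    """Configuration file failed to parse or validate."""


class UnknownKeyError(ConfigError):
    """Configuration contains a key the schema does not define."""


class SelectionError(PepGaMDError, IndexError):
    """A particle selection refers to indices that do not exist."""


class SuperpositionDegeneracyError(PepGaMDError):
    """Point set is too degenerate (collinear) for rigid-body superposition."""
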