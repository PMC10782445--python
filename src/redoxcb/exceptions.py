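"""Exception hierarchy.

Data-shaped problems (bad files, mixed systems, missing columns) raise
:class:`DataError`; estimator failures that a longer simulation would fix
(no histogram overlap, unbracketable BAR root) raise
:class:`ConvergenceError` or one of its subclasses.  The CLI maps
DataError to exit code 2 and ConvergenceError to exit code 3.
"""


class RedoxError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(RedoxError, ValueError):
    """A physical parameter is outside its domain (T <= 0, n_electrons < 1, ...)."""


class DataError(RedoxError, ValueError):
    """Malformed or inconsistent input data."""


class UnsupportedMethodError(RedoxError, ValueError):
    """The requested estimator cannot be applied to this data (e.g. one-sided set)."""


class ConvergenceError(RedoxError, RuntimeError):
    """An iterative estimator failed to converge or bracket its solution."""


class NoCrossingError(ConvergenceError):
    """Forward and negated-backward work histograms do not overlap / never cross."""


class DegenerateCrossingError(ConvergenceError):
    """Histograms coincide everywhere; the crossing point is undefined."""


class IllConditionedFitError(ConvergenceError):
    """Titration data do not constrain the sigmoid (single-plateau curve)."""


class UndefinedCorrelationError(RedoxError, ValueError):
    """Pearson correlation requested for a zero-variance sequence."""
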