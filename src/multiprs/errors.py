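"""Exception hierarchy.

The CLI maps :class:`InputError` to exit code 2 and
:class:`NumericalError` (and subclasses) to exit code 3.
"""


class MultiprsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MultiprsError):
    """Invalid or internally inconsistent configuration."""


class InputError(MultiprsError):
    """Malformed or missing input data."""


class AlignmentError(InputError):
    """Individual or variant sets that should match do not."""


class AmbiguityError(InputError):
    """Conflicting variant definitions at the same genomic position."""


class NumericalError(MultiprsError):
    """Numerical failure (singularity, non-convergence, degeneracy)."""


class CollinearityError(NumericalError):
    """Rank-deficient design matrix; carries the offending column names."""

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(message or f"collinear design columns: {self.columns}")


class ConvergenceError(NumericalError):
    """Iterative fit failed to converge; carries the iteration trace."""

    def __init__(self, message, trace=None):
        self.trace = trace
        super().__init__(message)


class ZeroVarianceError(NumericalError):
    """A quantity that must have positive variance is constant."""


class UnidentifiableError(NumericalError):
    """Model parameters not identifiable from the given design."""
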