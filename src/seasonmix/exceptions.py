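"""Exception hierarchy.

``InputError`` maps to CLI exit code 2, ``ConvergenceError`` to 3.
"""


class SeasonmixError(Exception):
    """Base class for all package errors."""


class InputError(SeasonmixError, ValueError):
    """Malformed or inconsistent user input (bad table, unknown label, ...)."""


class DegenerateInputError(InputError):
    """Input that is formally valid but statistically degenerate
    (constant vector passed to standardize, all-zero counts, ...)."""


class NoSeasonalityError(DegenerateInputError):
    """Both harmonic coefficients are zero: no seasonal phase is defined."""


class SingularDesignError(InputError):
    """Rank-deficient design matrix."""


class ConvergenceError(SeasonmixError):
    """An iterative fit failed to converge; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class FitError(SeasonmixError):
    """A model fit failed outright (all mixture restarts, a GLM, ...)."""
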