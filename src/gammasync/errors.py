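"""Exception hierarchy for the gammasync pipeline."""


class GammaSyncError(Exception):
    """Base class for all gammasync errors."""


class InvalidBandError(GammaSyncError, ValueError):
    """Band-pass corner frequencies are outside (0, Nyquist) or unordered."""


class DegenerateSignalError(GammaSyncError, ValueError):
    """A signal is constant (zero variance) where oscillation is required."""


class InsufficientCyclesError(GammaSyncError, ValueError):
    """Too few half-cycle boundaries were found for the requested analysis."""


class DegenerateWindowError(GammaSyncError, ValueError):
    """A correlation window has zero variance in one of its segments."""


class EdgeWindowError(GammaSyncError, ValueError):
    """A lag-shifted segment would fall outside the recorded epoch."""


class DegenerateCorrelationError(GammaSyncError, ValueError):
    """|r| = 1 leaves the Fisher z transform undefined."""


class AlignmentError(GammaSyncError, ValueError):
    """Two series expected on a common time grid do not match."""


class OptimizationFailureError(GammaSyncError, RuntimeError):
    """Likelihood maximization failed to converge.

    Carries the best parameter vector found so far in ``best_params``.
    """

    def __init__(self, message, best_params=None):
        super().__init__(message)
        self.best_params = best_params


class StarvedComponentError(GammaSyncError, RuntimeError):
    """A mixture component's effective sample size is too small to refit."""


class NumericDegeneracyError(GammaSyncError, RuntimeError):
    """All component densities underflowed for some observation."""

    def __init__(self, message, row=None):
        super().__init__(message)
        self.row = row


class ConfigError(GammaSyncError, ValueError):
    """A run configuration is malformed or violates a module constraint."""
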