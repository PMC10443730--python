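"""Exception hierarchy for the simulator."""


class GuytonSimError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(GuytonSimError):
    """A parameter violates a physical or structural constraint."""


class InvalidInputError(GuytonSimError):
    """A structurally malformed input (empty list, unknown name, bad grid)."""


class NoEquilibriumError(GuytonSimError):
    """The two curves admit no positive-flow intersection (P_PC >= P_MSF)."""


class ConvergenceError(GuytonSimError):
    """Fixed-point iteration failed to converge.

    Carries the last iterate so callers can inspect how close it got.
    """

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class NondifferentiablePointError(GuytonSimError):
    """Operating point sits on a curve breakpoint; partials are undefined."""


class GenerationError(GuytonSimError):
    """Synthetic-cohort rejection sampling exceeded its cap."""
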