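"""Exception hierarchy for kinetic-modelling failures."""


class PibTransferError(Exception):
    """Base class for all package errors."""


class InvalidInputError(PibTransferError, ValueError):
    """Input violates a structural precondition (ordering, span, sign)."""


class DegenerateInputError(PibTransferError, ValueError):
    """Input is structurally valid but numerically degenerate (e.g. ca(T) = 0)."""


class InsufficientDataError(PibTransferError, ValueError):
    """Too few observations for the requested fit or summary."""


class ConvergenceError(PibTransferError, RuntimeError):
    """Iterative fit failed to converge; carries the best solution found."""

    def __init__(self, message, best_fit=None):
        super().__init__(message)
        self.best_fit = best_fit


class DomainError(PibTransferError, ValueError):
    """Argument outside the mathematical domain of a transfer relation."""
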