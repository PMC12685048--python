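"""Exception hierarchy shared across the package."""


class PhytoswitchError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(PhytoswitchError, ValueError):
    """An argument violates a documented precondition."""


class InvalidStateError(PhytoswitchError, ValueError):
    """A state vector violates its invariants (e.g. negative concentration)."""


class DegenerateInputError(PhytoswitchError, ValueError):
    """All driving rates vanish; the requested quantity is undefined."""


class IntegrationError(PhytoswitchError, RuntimeError):
    """The ODE solver failed to converge.

    Carries the index of the offending protocol segment in ``segment_index``.
    """

    def __init__(self, message, segment_index=None):
        super().__init__(message)
        self.segment_index = segment_index


class InsufficientDataError(PhytoswitchError, ValueError):
    """Too few usable samples for the requested estimate."""


class ZeroFluxInferenceError(PhytoswitchError, ValueError):
    """Actinometer trace has zero slope; photon flux cannot be inferred."""


class NoDecayError(PhytoswitchError, ValueError):
    """Trace does not decay; decay fit is undefined."""


class NoRecoveryError(PhytoswitchError, ValueError):
    """Trace does not recover; recovery fit is undefined."""


class FitFailureError(PhytoswitchError, RuntimeError):
    """Nonlinear fit failed to converge; diagnostics in the message."""


class MarkupError(PhytoswitchError, ValueError):
    """Protocol markup is missing or inconsistent with the trace."""


class AmbiguousPeakError(PhytoswitchError, ValueError):
    """Line profile lacks a single dominant peak."""


class AnchorError(PhytoswitchError, ValueError):
    """Spectrum has no usable absorbance at the anchoring wavelength."""


class SchemaError(PhytoswitchError, ValueError):
    """A delimited-text table does not match its declared schema."""
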