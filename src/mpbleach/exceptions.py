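"""Exception and warning types shared across the package."""


class MPBleachError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(MPBleachError, ValueError):
    """A physical parameter is outside its admissible range."""


class ParameterMissingError(MPBleachError, ValueError):
    """A molecular parameter required by the requested operation is unset."""


class UnsupportedOrderError(MPBleachError, ValueError):
    """The requested multiphoton order is outside the supported set."""


class InsufficientDataError(MPBleachError, ValueError):
    """Too few usable data points for the requested fit or transform."""


class NonIdentifiableError(MPBleachError, RuntimeError):
    """The data carry no information on a parameter (flat likelihood)."""


class UnconstrainedFitError(MPBleachError, ValueError):
    """The scan does not constrain the model (e.g. edge outside the scan)."""


class RegimeMismatchError(MPBleachError, RuntimeError):
    """The data are inconsistent with the assumed kinetic regime."""


class FitConvergenceError(MPBleachError, RuntimeError):
    """A nonlinear fit failed to converge."""


class ValidationError(MPBleachError, ValueError):
    """Malformed input file or configuration."""


class AccuracyWarning(UserWarning):
    """Numerical quadrature did not reach the requested tolerance."""


class DomainWarning(UserWarning):
    """A saturation approximation was evaluated outside its validity domain."""


class ContaminationWarning(UserWarning):
    """A fit segment appears contaminated by a different kinetic regime."""


class PlausibilityWarning(UserWarning):
    """A fitted parameter falls outside the instrument's plausible band."""
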