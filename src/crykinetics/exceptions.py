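"""Exception hierarchy for photocycle modeling errors."""


class CrykineticsError(Exception):
    """Base class for all package errors."""


class DomainError(CrykineticsError, ValueError):
    """A physical quantity is outside its valid domain (negative rate, ...)."""


class DataError(CrykineticsError, ValueError):
    """Measured data violate a physicality or format requirement."""


class FitError(CrykineticsError, RuntimeError):
    """A least-squares fit failed to converge or is ill-posed."""


class InversionError(CrykineticsError, RuntimeError):
    """An observed concentration is unattainable under the kinetic model,
    so no rate constant reproduces it."""
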