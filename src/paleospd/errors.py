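"""Exception hierarchy shared across the package."""


class PaleospdError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PaleospdError, ValueError):
    """A file or table violates the expected layout or invariants."""


class ArgumentError(PaleospdError, ValueError):
    """An argument violates a precondition (bad window, empty pool, ...)."""


class OutOfRangeError(PaleospdError, ValueError):
    """A measurement lies entirely outside the calibration curve support."""


class DegenerateDensityError(PaleospdError, ValueError):
    """A zero-error measurement matches no grid year exactly."""


class FitError(PaleospdError, RuntimeError):
    """A model fit failed to converge at every attempt."""
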