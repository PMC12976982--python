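"""Exception hierarchy shared across the package."""


class VDomainsError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(VDomainsError):
    """Invalid configuration values (bad intervals, negative scales, ...)."""


class ParameterError(VDomainsError):
    """Process-model parameter vector violates its invariants."""


class InputError(VDomainsError):
    """Caller passed unusable data (empty season set, length mismatch, ...)."""


class UnfillableSeasonError(VDomainsError):
    """A season's gaps cannot be interpolated (an entire variable missing)."""


class UnsupportedLatitudeError(VDomainsError):
    """Latitude beyond the polar circle: no sunrise/sunset every day."""


class GenerationError(VDomainsError):
    """Synthetic ground-truth generation produced an unviable dataset."""


class FitError(VDomainsError):
    """A statistical fit could not be performed (degenerate inputs)."""


class NumericError(VDomainsError):
    """Non-finite intermediate in a numerical recurrence."""
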