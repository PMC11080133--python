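"""Exception hierarchy shared across the package."""


class VoltaChemoError(Exception):
    """Base class for all package errors."""


class FormatError(VoltaChemoError, ValueError):
    """Malformed on-disk data (ragged CSV rows, non-uniform potential grid, ...)."""


class DomainError(VoltaChemoError, ValueError):
    """Input violates a mathematical precondition (negative concentration, ...)."""


class ConfigurationError(VoltaChemoError, ValueError):
    """Inconsistent or unsupported parameter combination."""


class DegenerateSystemError(VoltaChemoError, ValueError):
    """A linear system or model has no usable solution (all-zero weights,
    singular score covariance, zero-variance response, ...)."""
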