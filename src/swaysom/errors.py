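"""Exception types shared across the package."""


class SwaysomError(Exception):
    """Base class for all package-specific errors."""


class MalformedInputError(SwaysomError, ValueError):
    """Raised when an input recording violates its structural contract
    (too few frames, non-monotone timestamps, missing body segments)."""


class NoCyclesError(SwaysomError, ValueError):
    """Raised when no sway cycles can be identified in a trial."""


class DegenerateTrialError(SwaysomError, ValueError):
    """Raised when a trial has zero mean amplitude for some coordinate,
    which would make the amplitude normalization divide by zero."""


class ConfigurationError(SwaysomError, ValueError):
    """Raised for invalid cohort / pipeline configuration."""
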