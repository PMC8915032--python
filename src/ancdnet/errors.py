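"""Exception types used across the package."""


class AncdError(Exception):
    """Base class for all package errors."""


class NetworkLoadError(AncdError):
    """Raised when a case dataset cannot be parsed or fails validation."""


class ValidationError(AncdError):
    """Raised when a domain object violates one of its invariants."""


class ConfigurationError(AncdError):
    """Raised for invalid solver/objective/scenario configuration."""
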