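"""Exception types shared across the package."""


class WoundTwinError(Exception):
    """Base class for package errors."""


class ConfigurationError(WoundTwinError):
    """Invalid configuration: bad preset label, malformed parameter file, bad scenario."""


class DomainError(WoundTwinError, ValueError):
    """An operation was called outside its mathematical domain."""


class IntegrationError(WoundTwinError, RuntimeError):
    """The integrator produced a non-finite derivative or state."""


class UsageError(WoundTwinError):
    """An operation was called on degenerate input (e.g. an empty trajectory)."""
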