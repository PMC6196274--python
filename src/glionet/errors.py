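"""Exception hierarchy shared across the package."""


class GlionetError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(GlionetError, ValueError):
    """An input violates a documented precondition or invariant."""


class ConfigurationError(GlionetError, ValueError):
    """A user-supplied configuration object (e.g. a logic table) is inconsistent."""


class ResourceError(GlionetError, RuntimeError):
    """A computation would exceed the configured resource budget."""
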