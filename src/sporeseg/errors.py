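"""Exception types shared across the package."""


class SporesegError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SporesegError):
    """A configuration object violates its invariants."""


class IntegrityError(SporesegError):
    """A persisted model directory is inconsistent or incomplete."""
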