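"""Exception hierarchy shared across the pipeline."""


class SeedboxError(Exception):
    """Base class for all package-specific errors."""


class DegenerateInputError(SeedboxError, ValueError):
    """An input record is structurally valid but carries no usable signal
    (all-black patch, empty mask, ...)."""


class ConfigurationError(SeedboxError, ValueError):
    """A parameter, name or file layout the user supplied is invalid."""


class DomainError(SeedboxError, ValueError):
    """A value lies outside the documented domain of an operation."""


class InsufficientReplicationError(SeedboxError, ValueError):
    """A factor level has too few observations for the requested test."""
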