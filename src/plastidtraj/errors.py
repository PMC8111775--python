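"""Exception hierarchy shared across the pipeline stages."""


class PlastidTrajError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PlastidTrajError):
    """A configuration value is invalid; the message names the field."""


class ArgumentError(PlastidTrajError, ValueError):
    """A numeric argument violates a precondition."""


class RangeError(ArgumentError):
    """A value lies outside the supported domain (e.g. a lookup table)."""


class FitError(PlastidTrajError):
    """A model fit cannot be carried out on the supplied data."""


class DependencyError(PlastidTrajError):
    """A pipeline stage was requested without the stage it depends on."""
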