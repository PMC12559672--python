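"""Exception hierarchy shared across the package."""


class MetapatchError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MetapatchError):
    """A tabular input does not have the expected structure."""


class ValidationError(MetapatchError):
    """A value violates a domain invariant (negative count, bad fraction...)."""


class UndefinedMetricError(MetapatchError):
    """A metric is mathematically undefined for the given input."""


class ConfigError(MetapatchError):
    """A configuration file violates the schema."""
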