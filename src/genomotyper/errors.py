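"""Exception hierarchy for genomotyper."""


class GenomotyperError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GenomotyperError):
    """A tabular input file violates the expected schema."""


class ConfigError(GenomotyperError):
    """A configuration value or combination of values is invalid."""


class FitError(GenomotyperError):
    """The presence-model fit cannot be computed on the given data."""
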