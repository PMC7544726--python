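"""Exception hierarchy shared across the package."""


class RadpocError(Exception):
    """Base class for all package errors."""


class InputError(RadpocError, ValueError):
    """Invalid user-supplied data (doses, years, ages, rates)."""


class ConfigurationError(RadpocError, ValueError):
    """Invalid model-set or run configuration."""
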