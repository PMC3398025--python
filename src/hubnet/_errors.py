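"""Exception hierarchy shared across the pipeline stages."""


class HubnetError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(HubnetError):
    """Invalid or inconsistent run configuration."""


class DataError(HubnetError):
    """Malformed, missing or degenerate input data."""


class NumericalError(HubnetError):
    """A model fit or statistic could not be computed."""
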