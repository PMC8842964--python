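"""Exception types shared across the package."""


class PangotraceError(Exception):
    """Base class for all package-specific errors."""


class DataError(PangotraceError):
    """Malformed or inconsistent input data."""


class ConfigError(PangotraceError):
    """Invalid configuration or parameter values."""
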