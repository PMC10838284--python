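"""Exception hierarchy shared across the package."""


class RadbenchError(Exception):
    """Base class for all package errors."""


class FormatError(RadbenchError, ValueError):
    """Malformed input file (bad CSV layout, duplicate columns, ...)."""


class DataError(RadbenchError, ValueError):
    """Structurally valid input that violates a data contract."""


class ConfigError(RadbenchError, ValueError):
    """Invalid configuration or an infeasible specification."""
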