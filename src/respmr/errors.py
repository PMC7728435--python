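"""Exception hierarchy shared across the pipeline.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class RespmrError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(RespmrError):
    """Invalid configuration or parameter value."""


class DataError(RespmrError):
    """Input data violates a precondition (missing columns, empty joins, ...)."""


class SimulationError(RespmrError):
    """A stochastic generator produced an unusable draw (e.g. zero cases)."""
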