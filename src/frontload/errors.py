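"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
InvariantError -> 4.
"""


class FrontloadError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(FrontloadError):
    """Invalid configuration (bad parameter values, inconsistent design)."""


class DataError(FrontloadError):
    """Invalid or unusable input data (missing groups, malformed tables)."""


class InvariantError(FrontloadError):
    """An internal consistency check failed; indicates a bug, not bad input."""
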