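"""Exception hierarchy for the offload pipeline.

Exit-code mapping used by the CLI: SchemaError -> 2, NumericalError -> 3.
"""


class OffloadError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(OffloadError):
    """Invalid configuration (non-positive SD, impossible bounds, bad paths)."""


class SchemaError(OffloadError):
    """Malformed input table: missing column, bad cell, broken invariant.

    Messages name the offending column and, where known, the row.
    """


class MissingDataError(OffloadError):
    """A required slice of the data (e.g. a forced condition) is absent."""


class NumericalError(OffloadError):
    """A numeric procedure failed (undefined test, rank deficiency,
    non-convergent integration)."""
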