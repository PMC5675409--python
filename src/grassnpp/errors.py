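"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: ConfigError -> 2,
MissingInputError -> 3, NumericalError -> 4.
"""


class GrassNppError(Exception):
    """Base class for all package errors."""


class ConfigError(GrassNppError, ValueError):
    """Invalid configuration or constructor arguments."""


class GridMismatchError(GrassNppError, ValueError):
    """Two gridded products do not share the same raster grid."""


class MissingInputError(GrassNppError, FileNotFoundError):
    """A required input file or month is absent."""


class DataValidationError(GrassNppError, ValueError):
    """Input records violate a physical or schema constraint."""


class NumericalError(GrassNppError, ArithmeticError):
    """A computation could not produce a valid result."""
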