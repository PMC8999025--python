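"""Exception hierarchy for nirsconn."""


class NirsconnError(Exception):
    """Base class for all nirsconn errors."""


class InvalidParameterError(NirsconnError, ValueError):
    """A configuration or function parameter is outside its valid domain."""


class InvalidInputError(NirsconnError, ValueError):
    """Input data violate a precondition (wrong shape, non-finite, too short...)."""


class InvalidChannelError(InvalidInputError):
    """A channel index is outside the montage."""


class UndefinedCorrelationError(NirsconnError, ValueError):
    """Pearson correlation is undefined (zero-variance series)."""


class DegenerateTestError(NirsconnError):
    """A paired test is degenerate (zero-variance, non-zero-mean differences)."""


class ConfigurationError(NirsconnError):
    """Invalid run configuration (e.g. singular extinction matrix)."""


class DataError(NirsconnError):
    """File-level data problem (missing file, malformed table...)."""


class InconsistencyError(NirsconnError, ValueError):
    """Internal consistency check failed (e.g. group counts do not sum to total)."""
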