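"""Exception types shared across the package."""


class GliasyncError(Exception):
    """Base class for all package errors."""


class ParameterError(GliasyncError, ValueError):
    """A configuration or call parameter violates its documented constraints."""


class DataError(GliasyncError, ValueError):
    """Input data is malformed (non-finite values, wrong shape, empty, ...)."""


class UndefinedCorrelationError(GliasyncError, ValueError):
    """A correlation is undefined for the given inputs (constant or zero-norm trace)."""


class DegenerateDataError(GliasyncError, ValueError):
    """The data is degenerate for the requested statistic (e.g. all angles tied)."""
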