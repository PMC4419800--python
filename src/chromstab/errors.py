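"""Exception hierarchy.

All errors raised by this package derive from :class:`ChromstabError` so
callers can catch package failures with a single except clause while still
distinguishing bad inputs from bad configuration.
"""


class ChromstabError(Exception):
    """Base class for all chromstab errors."""


class InputError(ChromstabError):
    """The data handed to an operation violates its contract."""


class ConfigurationError(ChromstabError):
    """Parameters, thresholds or config files are invalid."""


class ComputationError(ChromstabError):
    """An operation was applied to data it cannot process (e.g. a density
    ratio over a zero denominator on unfiltered records)."""


class GeneLookupError(ChromstabError, KeyError):
    """A requested gene is absent from the structure being queried."""
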