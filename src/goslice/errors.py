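"""Exception hierarchy.

All domain errors derive from :class:`GosliceError` so callers (and the CLI)
can distinguish domain failures (exit code 1) from I/O and usage failures
(exit code 2).
"""


class GosliceError(Exception):
    """Base class for all domain errors raised by this package."""


class OboParseError(GosliceError):
    """Malformed OBO input; message names the offending line."""


class GraphCycleError(GosliceError):
    """Scoping edges form a cycle after orientation; message names one cycle."""


class UnknownTermError(GosliceError, KeyError):
    """A term id was looked up that is not in the graph's node index."""

    def __str__(self) -> str:  # KeyError repr-quotes its message
        return Exception.__str__(self)


class CategorizationError(GosliceError):
    """No representative could be elected for a category."""


class ConfigurationError(GosliceError):
    """Inconsistent user configuration (duplicate representatives, etc.)."""


class GafFormatError(GosliceError):
    """Malformed GAF record; message carries the line number."""


class UndefinedValueError(GosliceError, ValueError):
    """A set statistic was requested on inputs for which it is undefined."""
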