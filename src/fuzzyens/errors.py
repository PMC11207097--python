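"""Exception hierarchy.

All fuzzyens-specific errors derive from :class:`FuzzyEnsError` so callers can
catch the whole family; the concrete classes also subclass the closest builtin
(ValueError / RuntimeError) to stay friendly to generic error handling.
"""


class FuzzyEnsError(Exception):
    """Base class for all fuzzyens errors."""


class TopologyError(FuzzyEnsError, ValueError):
    """Topology inconsistent with itself or with coordinate data."""


class FormatError(FuzzyEnsError, ValueError):
    """A file could not be parsed as the expected format."""


class FitError(FuzzyEnsError, RuntimeError):
    """A nonlinear fit failed to converge or the data are degenerate."""


class PackingError(FuzzyEnsError, RuntimeError):
    """Random placement of molecules in a box failed after the attempt budget."""
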