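"""Exception hierarchy.

All errors derive from :class:`ManiaError` so callers can catch broadly.
``ValidationError`` maps to CLI exit code 2, ``DegenerateInputError`` to 3.
"""


class ManiaError(ValueError):
    """Base class for all package-specific errors."""


class ValidationError(ManiaError):
    """Malformed or inconsistent input (shapes, ranges, labels)."""


class UndefinedMetricError(ManiaError):
    """A metric is mathematically undefined for this input (e.g. 0/0)."""


class DegenerateInputError(ManiaError):
    """Input admits no eligible solution (all-empty or all-complete scans)."""


class NoSignalError(DegenerateInputError):
    """Every connection strength is zero; no network can be inferred."""
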