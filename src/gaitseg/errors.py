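"""Exception hierarchy for gaitseg.

All package errors derive from :class:`GaitSegError` so callers (and the
CLI) can distinguish domain failures from programming errors.
"""


class GaitSegError(Exception):
    """Base class for all gaitseg errors."""


class FormatError(GaitSegError):
    """Malformed input file (missing column, non-monotone counter, ...)."""


class RecordingInvalidError(GaitSegError):
    """Recording violates an exclusion rule (e.g. sensor gap > 0.5 s)."""


class FilterError(GaitSegError):
    """Sequence too short (or otherwise unsuitable) for filtering."""


class ArgumentError(GaitSegError, ValueError):
    """Invalid argument value."""


class SignalTooShortError(GaitSegError):
    """Signal shorter than the minimum required by an operation."""


class DegenerateSignalError(GaitSegError):
    """Signal degenerate for the requested operation (e.g. all-zero omega)."""


class ConstraintError(GaitSegError):
    """No warping path satisfies the global (Itakura) constraint."""
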