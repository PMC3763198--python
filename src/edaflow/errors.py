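"""Typed exceptions raised across the pipeline.

Every stage rejects invalid input with one of these rather than silently
coercing; the hierarchy lets callers catch all package errors at once
(``EdaflowError``) or a specific failure mode.
"""


class EdaflowError(Exception):
    """Base class for all edaflow errors."""


class ConfigurationError(EdaflowError, ValueError):
    """A configuration value is invalid; the message names the field."""


class ParseError(EdaflowError, ValueError):
    """An on-disk artifact could not be parsed; includes line/row context."""


class RangeViolationError(ParseError):
    """A rating lies outside its scale bounds; the message names the row."""


class LayoutError(EdaflowError, ValueError):
    """A session layout is inconsistent with the trace or the design."""


class DegenerateSegmentError(EdaflowError, ValueError):
    """A detrending segment has too few samples for a line fit."""


class DegenerateRangeError(EdaflowError, ValueError):
    """Range correction is undefined: the trace is constant (max == min)."""


class AlignmentError(EdaflowError, ValueError):
    """Ratings and layout disagree on the trial structure."""


class ResourceError(EdaflowError, RuntimeError):
    """A simulated session would exceed the configured maximum duration."""


class UndefinedTestError(EdaflowError, ValueError):
    """A statistical test is undefined for the given data (e.g. all-zero
    differences in a signed-rank test)."""


class EmptyReportError(EdaflowError, ValueError):
    """No subjects survived inclusion/exclusion; no report can be built."""
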