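"""Exception hierarchy for reefmetrics.

Every error raised by the library derives from :class:`ReefMetricsError`
so callers (and the CLI) can distinguish input/format problems from
numerical/degenerate-geometry problems.
"""


class ReefMetricsError(Exception):
    """Base class for all reefmetrics errors."""


class FormatError(ReefMetricsError):
    """Unreadable or malformed input file (STL dialect, truncation, CSV schema)."""


class SchemaError(FormatError):
    """A tabular input is missing required columns or rows."""


class DegenerateInputError(ReefMetricsError):
    """Geometry too degenerate to process (empty mesh, coplanar hull input)."""


class ParameterError(ReefMetricsError):
    """An argument is outside its documented domain."""


class InconsistencyError(ReefMetricsError):
    """Internally inconsistent quantities (e.g. mesh volume exceeding hull volume)."""


class ConfigurationError(ReefMetricsError):
    """Unknown scheme/mode name or invalid configuration combination."""


class InsufficientScaleRangeError(ParameterError):
    """Too few usable box sizes to fit a box-counting slope."""
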