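"""Exception hierarchy for the toolgaze pipeline.

Every stage raises a subclass of :class:`ToolgazeError` so the pipeline
driver can abort with the failing stage named.
"""


class ToolgazeError(Exception):
    """Base class for all toolgaze errors."""


class ConfigurationError(ToolgazeError, ValueError):
    """Invalid run configuration or generator parameters."""


class FormatError(ToolgazeError, ValueError):
    """A delimited input file violates the documented schema."""


class DialectError(FormatError):
    """Unknown column layout / delimiter dialect."""


class GeometryError(ToolgazeError, ValueError):
    """Degenerate scene geometry (e.g. coincident cylinder endpoints)."""


class AlignmentError(ToolgazeError, ValueError):
    """Gaze, annotation and event streams do not overlap in time."""


class InsufficientDataError(ToolgazeError, ValueError):
    """Not enough subjects/sessions/points for the requested statistic."""
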