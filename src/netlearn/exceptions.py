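"""Exception hierarchy for the netlearn pipeline.

Every stage raises a subclass of :class:`NetlearnError`, so callers (and the
CLI) can distinguish bad input (exit code 1) from computation failures
(exit code 2) without string matching.
"""


class NetlearnError(Exception):
    """Base class for all netlearn errors."""


class InputError(NetlearnError):
    """Problems with user-supplied files or tables (CLI exit code 1)."""


class FormatError(InputError):
    """A file could not be parsed in any supported dialect."""


class DegenerateInputError(NetlearnError):
    """Input is syntactically valid but unusable (too short, all-zero, ...)."""


class ParameterError(NetlearnError):
    """A configuration or method parameter is out of its admissible range."""


class ShapeError(NetlearnError):
    """Array arguments have incompatible shapes or lengths."""


class LookupError_(InputError):
    """A requested label (task, subject) is absent from a table."""


class BoundsError(NetlearnError):
    """A requested segment extends beyond the available recording."""


class DisconnectedNetworkError(NetlearnError):
    """Average shortest path length requested for a disconnected graph."""


class DegenerateStatisticError(NetlearnError):
    """A test statistic is undefined (zero variance, constant input)."""


class IncompleteDesignError(NetlearnError):
    """A repeated-measures design has missing cells."""
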