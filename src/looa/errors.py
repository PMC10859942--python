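"""Exception hierarchy shared across the package."""


class LooaError(Exception):
    """Base class for all package-specific errors."""


class InputError(LooaError):
    """A required input file is missing or unreadable."""


class FormatError(LooaError):
    """The input violates the Source/Target CSV contract."""


class EmptyGraphError(LooaError):
    """Every record was dropped; no graph can be built."""


class GraphSizeError(LooaError):
    """The graph is too small for the requested analysis."""


class ConvergenceError(LooaError):
    """An iterative numerical routine failed to converge."""


class DegenerateDataError(LooaError):
    """Too few non-constant delta columns for a correlation PCA."""


class ParameterError(LooaError):
    """A user-supplied parameter is out of its valid range."""


class OutputError(LooaError):
    """An output path cannot be written."""
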