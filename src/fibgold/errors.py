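"""Exception hierarchy shared across the pipeline stages."""


class FibgoldError(Exception):
    """Base class for all package errors."""


class FormatError(FibgoldError):
    """A volume file could not be read or written in the requested format."""


class ShapeError(FormatError):
    """Pages/sections of a stack have inconsistent shapes."""


class SchemaError(FibgoldError):
    """A particle table is missing mandatory columns."""


class ConfigError(FibgoldError):
    """Invalid configuration (geometry, densities, stage parameters)."""


class SegmentationError(FibgoldError):
    """Region tracing or threshold selection failed."""


class AssignmentError(FibgoldError):
    """A particle centroid falls outside the label volume."""
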