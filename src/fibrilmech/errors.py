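"""Exception hierarchy for fibrilmech."""


class FibrilMechError(Exception):
    """Base class for all fibrilmech errors."""


class ParseError(FibrilMechError):
    """A file could not be parsed (malformed record, bad count line, ...)."""


class StructureError(FibrilMechError):
    """Inconsistent topology, e.g. atom count changes between frames."""


class SelectionError(FibrilMechError):
    """An atom selection matched nothing."""


class WindowError(FibrilMechError):
    """Frame windowing produced an empty trajectory."""


class GeometryError(FibrilMechError):
    """Degenerate geometry (zero-length axis, too few points, ...)."""


class ConfigError(FibrilMechError):
    """Invalid analysis configuration."""
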