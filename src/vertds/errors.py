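"""Exception hierarchy for vertds."""


class VertdsError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(VertdsError, ValueError):
    """An input object violates its declared invariants."""


class DegenerateGeometryError(VertdsError, ValueError):
    """Geometry too degenerate to process (collinear points, constant image...)."""


class EmptyResultError(VertdsError, ValueError):
    """An operation removed or produced no data; carries a diagnostic message."""
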