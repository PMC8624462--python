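"""Exception hierarchy for cephrr."""


class CephrrError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CephrrError, ValueError):
    """Input data violates a structural contract (schema, uniqueness, range)."""


class ParseError(CephrrError, ValueError):
    """An annotation file could not be parsed; message names the offending
    line or element."""


class DegenerateGeometryError(CephrrError, ValueError):
    """Collinear or coincident points where a plane or frame is required."""


class OrientationAmbiguousError(DegenerateGeometryError):
    """The orientation hint is orthogonal to the plane normal, so the sign
    of the normal cannot be fixed."""


class MissingLandmarkError(CephrrError, KeyError):
    """A required landmark has no usable observation."""
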