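"""Exception hierarchy for the reconstruction pipeline."""

__all__ = [
    "TorsoscanError",
    "InvalidParameterError",
    "DegenerateGeometryError",
    "ReconstructionError",
    "MeshingError",
    "ParseError",
    "EmptyResultError",
]


class TorsoscanError(Exception):
    """Base class for package errors."""


class InvalidParameterError(TorsoscanError, ValueError):
    """A parameter violates a documented precondition."""


class DegenerateGeometryError(TorsoscanError):
    """Geometry does not determine a solution (zero baseline, parallel rays,
    collinear correspondences, ...)."""


class ReconstructionError(TorsoscanError):
    """A reconstruction stage failed (initialization, registration, ...)."""


class MeshingError(TorsoscanError):
    """Surface meshing could not proceed on the given cloud."""


class ParseError(TorsoscanError, IOError):
    """A file could not be parsed; the message names the offending line."""


class EmptyResultError(TorsoscanError):
    """An operation produced no usable output (e.g. zero electrodes)."""
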