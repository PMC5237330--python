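"""Exception hierarchy shared across the package."""


class ShapeAtlasError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ShapeAtlasError):
    """A file could not be parsed as a supported 3D volume."""


class ContentError(ShapeAtlasError):
    """Volume content violates a precondition (empty/full shape, bad labels...)."""


class FrameError(ShapeAtlasError):
    """Volumes are not on a common grid (dims/spacing/origin mismatch)."""


class DomainError(ShapeAtlasError, ValueError):
    """A scalar argument is outside its admissible range."""


class SpecError(ShapeAtlasError):
    """A synthetic-population specification is inconsistent or produces clipped shapes."""


class UndefinedMeasureError(ShapeAtlasError):
    """A similarity measure is undefined for the given operands."""


class PairingError(ShapeAtlasError):
    """Evaluation records cannot be paired case-by-case across methods."""
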