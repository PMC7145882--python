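"""Exception types shared across the pipeline."""


class BoneStrainError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(BoneStrainError):
    """Requested geometry does not fit the image extent."""


class SegmentationError(BoneStrainError):
    """No vertebral component found above the BMD threshold."""


class AmbiguityError(BoneStrainError):
    """More segmented components than available vertebral labels."""

    def __init__(self, message: str, candidates=None):
        super().__init__(message)
        self.candidates = candidates or []


class GeometryError(BoneStrainError):
    """Degenerate or invalid polygon/mesh geometry."""


class SolverError(BoneStrainError):
    """The finite-element system could not be solved."""
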