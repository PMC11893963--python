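"""Exception hierarchy for the LSF pipeline.

Hard contract violations (wrong grids, mixed frames of reference, undefined
ratios) raise; recoverable oddities (empty resampled mask, zero posterior
counts) only warn through the ``lsfquant`` logger.
"""


class LSFError(Exception):
    """Base class for all lsfquant errors."""


class GeometryError(LSFError):
    """Invalid or incompatible spatial geometry (non-invertible affine,
    non-orthonormal orientation, grid mismatch between images/masks)."""


class FrameOfReferenceError(GeometryError):
    """Two inputs do not share a DICOM frame of reference."""


class FormatError(LSFError):
    """Malformed or unsupported on-disk image data (non-uniform slice gap,
    mixed orientations, shape mismatch of a planar pair)."""


class SegmentationError(LSFError):
    """Threshold or external segmentation could not produce the requested
    organ masks."""


class ExternalToolError(SegmentationError):
    """The configured external segmenter command failed; carries its log."""

    def __init__(self, message: str, log: str = ""):
        super().__init__(message)
        self.log = log


class MaskError(LSFError):
    """Organ masks violate a precondition (overlapping inputs, wrong grid)."""


class UndefinedLSFError(LSFError):
    """An LSF or percentage-difference ratio has a zero denominator."""


class ActivityError(LSFError):
    """Inconsistent assayed activities (negative net activity after residual
    subtraction and decay correction)."""


class PhantomError(LSFError):
    """Invalid digital-phantom specification (overlapping compartments,
    negative activities)."""


class ReportError(LSFError):
    """A mandatory report field is missing or inconsistent."""
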