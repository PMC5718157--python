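"""Exception hierarchy for dopplerwss."""


class DopplerWSSError(Exception):
    """Base class for all dopplerwss errors."""


class CalibrationError(DopplerWSSError, ValueError):
    """Missing or invalid physical calibration (pixel spacing, Nyquist velocity)."""


class FormatError(DopplerWSSError, ValueError):
    """Input file is not a supported RGB Doppler frame."""


class ColorMapError(DopplerWSSError, ValueError):
    """Colormap specification violates its invariants."""


class SegmentationError(DopplerWSSError, RuntimeError):
    """Lumen/wall segmentation failed (no flow, no wall-bounded columns)."""


class ResolutionError(DopplerWSSError, ValueError):
    """Requested phantom geometry is below the minimum resolvable size."""
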