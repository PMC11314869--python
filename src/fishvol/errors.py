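"""Exception hierarchy shared across the pipeline."""


class FishvolError(Exception):
    """Base class for all package-specific errors."""


class CalibrationError(FishvolError):
    """Calibration file missing, malformed, or violating invariants."""


class InvalidDepthError(FishvolError):
    """A nonpositive range value was used where a valid depth is required."""


class BehindCameraError(FishvolError):
    """A 3D point with z <= 0 cannot be projected to the pixel plane."""


class MaskFormatError(FishvolError):
    """Mask file unreadable, unknown format, or degenerate polygon."""


class EmptyMaskError(FishvolError):
    """No foreground pixels remain after reading/cleaning a mask."""


class RingEmptyError(FishvolError):
    """The perimeter ring around a mask contains no pixels."""


class QCRejection(FishvolError):
    """A frame failed a quality-control gate.

    ``reason`` is a short machine-readable code used in the pipeline's QC
    log: ``empty-mask``, ``ring-empty``, ``ring-invalid``,
    ``invalid-depth-excess``.
    """

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        self.detail = detail
        super().__init__(f"{reason}: {detail}" if detail else reason)
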