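"""Exception taxonomy for the pipeline.

Every rejection a stage can issue has its own class so that the pipeline
can record a per-case exclusion reason instead of silently dropping cases.
"""


class DopplerQuantError(Exception):
    """Base class for all package errors."""


class CalibrationError(DopplerQuantError):
    """Calibration sidecar missing, unreadable, or violating an invariant."""


class FrameError(DopplerQuantError):
    """Frame stack inconsistent (shape mismatch, empty, wrong dtype)."""


class RoiError(DopplerQuantError):
    """ROI mask degenerate (no pixel) or mismatched with the frames."""


class LutError(DopplerQuantError):
    """Colorbar lookup table invalid (duplicate RGB, non-monotone branch)."""


class OutOfRangeError(DopplerQuantError):
    """Velocity outside the colorbar range during encoding."""


class NoCompleteCycleError(DopplerQuantError):
    """Fewer than two systolic peaks: no complete cardiac cycle."""


class EmptyInputError(DopplerQuantError):
    """Empty trace or empty value vector."""


class NoVesselError(DopplerQuantError):
    """No perfused pixel in any frame: no vessel visible in the lesion."""


class VesselDirectionError(DopplerQuantError):
    """No candidate vessel has a temporally consistent flow direction."""


class AxisUndefinedError(DopplerQuantError):
    """Vessel mask too small or degenerate for axis estimation."""


class PerpendicularFlowError(DopplerQuantError):
    """Doppler angle of 90 degrees: flow perpendicular to the beam."""


class DegenerateSampleError(DopplerQuantError):
    """Constant or too-small sample handed to a statistical test."""


class InsufficientGroupError(DopplerQuantError):
    """A comparison group has fewer cases than the test requires."""


class SingleClassError(DopplerQuantError):
    """ROC analysis received only one class label."""


class InsufficientPairsError(DopplerQuantError):
    """Too few pairwise-complete cases for a paired AUC comparison."""


class FrameRateError(DopplerQuantError):
    """Frame rate too low to resolve the requested cardiac waveform."""


class GeometryError(DopplerQuantError):
    """Synthetic vessel geometry does not fit inside the ROI."""
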