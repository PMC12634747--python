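"""Exception hierarchy shared across the pipeline."""


class MaskScopeError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(MaskScopeError, ValueError):
    """Invalid parameter value (non-positive scale, out-of-range input...)."""


class ConvergenceError(MaskScopeError, RuntimeError):
    """An iterative calibration or fit failed to reach its target."""


class PlacementError(MaskScopeError, ValueError):
    """A lesion center falls outside the breast mask."""


class SegmentationError(MaskScopeError, RuntimeError):
    """Breast segmentation produced an empty mask."""


class ProcessingFailure(MaskScopeError, RuntimeError):
    """Exam-level failure: no view of an examination could be processed.

    Mirrors real-pipeline exclusions such as a missing open-beam reference
    or a breast implant; carries a machine-readable reason code.
    """

    def __init__(self, reason: str, message: str = ""):
        self.reason = reason
        super().__init__(message or reason)


class ValidationError(MaskScopeError, ValueError):
    """Inconsistent cohort record (e.g. diagnosis before examination)."""
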