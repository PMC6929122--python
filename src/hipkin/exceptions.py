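"""Exception hierarchy for hipkin.

Every error raised by the library derives from :class:`HipkinError` so that
pipeline callers can catch a single base class while tests can assert the
specific failure mode (degenerate geometry vs. insufficient data, etc.).
"""


class HipkinError(Exception):
    """Base class for all hipkin errors."""


class InvalidInputError(HipkinError, ValueError):
    """Non-finite or structurally invalid input."""


class InvalidParameterError(HipkinError, ValueError):
    """A configuration or call parameter is out of its valid range."""


class InsufficientDataError(HipkinError, ValueError):
    """A recording or selection is too short for the requested operation."""


class InvalidRotationError(HipkinError, ValueError):
    """A matrix is not a proper rotation within tolerance."""


class DegenerateAxisError(HipkinError, ValueError):
    """Rotation axis undefined (e.g. antiparallel vectors)."""


class DegenerateHeadingError(HipkinError, ValueError):
    """Horizontal magnetic-field component vanishes; heading unobservable."""


class DegenerateGeometryError(HipkinError, ValueError):
    """Joint-center geometry is degenerate (coincident centers)."""


class DegenerateMotionError(HipkinError, ValueError):
    """Calibration motion does not excite enough rotational degrees of freedom."""


class DegeneratePoseError(HipkinError, ValueError):
    """A calibration pose makes anatomical axes parallel."""


class SingularPoseError(HipkinError, ValueError):
    """Joint pose at the gimbal singularity of the joint coordinate system."""


class InitializationError(HipkinError, ValueError):
    """Filter initialization failed (e.g. free-fall accelerometer data)."""


class ConvergenceError(HipkinError, RuntimeError):
    """Iterative optimization failed to converge."""

    def __init__(self, message: str, final_cost: float | None = None):
        super().__init__(message)
        self.final_cost = final_cost


class NumericalError(HipkinError, RuntimeError):
    """A numerical invariant (e.g. covariance positive semidefiniteness) failed."""

    def __init__(self, message: str, sample_index: int | None = None):
        super().__init__(message)
        self.sample_index = sample_index


class PipelineStageError(HipkinError, RuntimeError):
    """Wraps an error from a named pipeline stage."""

    def __init__(self, stage: str, error: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {error}")
        self.stage = stage
        self.error = error
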