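"""Exception hierarchy.

Every error raised by the library derives from :class:`GaitmixError` so
batch drivers can catch analysis failures without masking programming
errors.  :class:`StageError` wraps a failure with the identity of the
pipeline stage that produced it, which the batch extractor uses to build
its exclusion accounting.
"""


class GaitmixError(Exception):
    """Base class for all gaitmix errors."""


class ParameterError(GaitmixError, ValueError):
    """A simulation or extraction parameter violates its invariants."""


class DegenerateInputError(GaitmixError, ValueError):
    """Input is structurally valid but too short/empty/constant to analyse."""


class FormatError(GaitmixError, ValueError):
    """A file or record does not conform to the expected dialect."""


class InsufficientStepsError(GaitmixError):
    """Fewer step events than the minimum needed for temporal statistics."""


class InconsistentEventsError(GaitmixError):
    """Step events are not strictly increasing in time."""


class InsufficientFramesError(GaitmixError):
    """Too few usable video frames remain after confidence filtering."""


class NoPeriodicityError(GaitmixError):
    """No autocorrelation peak found in the expected step/stride lag window."""


class DegenerateGeometryError(GaitmixError, ValueError):
    """Coincident keypoints make an angle undefined."""


class DesignError(GaitmixError, ValueError):
    """A cohort design or feature table is missing required structure."""


class SchemaError(GaitmixError, ValueError):
    """A tabular input is missing required columns."""


class CalibrationError(GaitmixError):
    """A generator parameter could not be calibrated to its target."""


class StageError(GaitmixError):
    """A pipeline stage failed; carries the stage name for reporting."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}': {cause}")
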