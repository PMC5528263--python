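"""Exception hierarchy.

Every failure mode the pipeline can hit has a named exception so callers
(and the CLI) can distinguish bad input from bad configuration from a
degenerate image.
"""


class TracmitError(Exception):
    """Base class for all package errors."""


class UnreadableImageError(TracmitError):
    """The input file could not be opened or parsed as a TIFF stack."""


class MultiChannelError(TracmitError):
    """The TIFF carries more than one channel (or RGB pages); the pipeline
    expects a single channel holding both pattern and chromatin signal."""


class TooFewFramesError(TracmitError):
    """A time-lapse needs at least two frames."""


class ConfigKeyError(TracmitError):
    """Unknown key in a configuration file."""


class ConfigValueError(TracmitError):
    """A configuration value violates its constraint (inverted band,
    non-positive scale, fraction outside (0, 1), ...)."""


class ConstantImageError(TracmitError):
    """An operation that needs intensity contrast received a constant
    image (thresholding, drift estimation)."""


class MaskCoverageError(TracmitError):
    """A pixel is valid in zero frames, so a temporal projection over
    valid frames is undefined there."""


class BimodalityError(TracmitError):
    """The intensity histogram never became bimodal within the smoothing
    iteration cap, so no intermodes threshold exists."""


class ZeroMeanError(TracmitError):
    """All pixels of an ROI have zero temporal mean; the fStDev occupancy
    score is undefined."""


class ProfileError(TracmitError):
    """Invalid line-profile request (coincident endpoints or points
    outside the image)."""


class SeedShapeError(TracmitError):
    """The seed blob handed to the backtracker fails the metaphase-plate
    shape bands — inconsistent upstream state."""


class GeometryError(TracmitError):
    """Synthetic-field geometry does not fit the requested image."""


class PipelineStageError(TracmitError):
    """Wraps an error raised inside a pipeline stage, recording which
    stage failed."""

    def __init__(self, stage: str, original: BaseException):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage {stage!r} failed: {original!r}")
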