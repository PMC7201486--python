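"""Exception hierarchy for the bird-dog scoring pipeline.

Every error names the offending trial/file/frame so that batch runs can
report failures per trial instead of dying silently.
"""


class BirddogError(Exception):
    """Base class for all package-specific errors."""


class FormatError(BirddogError):
    """A file or table does not follow the expected dialect."""


class MissingPersonError(BirddogError):
    """An OpenPose frame contains no detected person."""


class EmptyTrialError(BirddogError):
    """A trial directory contains no keypoint files."""


class AllMaskedError(BirddogError):
    """Every frame of a keypoint trajectory fell below the confidence threshold."""


class DegenerateBodyError(BirddogError):
    """Neck and hip keypoints coincide; body length is undefined."""


class DegenerateLimbError(BirddogError):
    """Limb origin and tip coincide; the limb angle is undefined."""


class TooShortError(BirddogError):
    """Fewer than two frames: per-frame displacement is undefined."""


class ConstantCohortError(BirddogError):
    """Zero variance across trials; the cohort z-score is undefined."""


class ConstantInputError(BirddogError):
    """A rank correlation of a constant sequence is undefined."""


class NoPostureError(BirddogError):
    """Heuristic timing never found a frame with the posture achieved."""


class MetadataError(BirddogError):
    """Inconsistent trial metadata (e.g. annotated fall before start)."""


class CollinearityError(BirddogError):
    """Regression design matrix is numerically collinear."""


class MissingRatingError(BirddogError):
    """The trial-by-rater table has missing cells."""
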