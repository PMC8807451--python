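"""Exception hierarchy for ctiq.

All package-specific failures derive from :class:`CTIQError` so callers can
catch everything with one clause while still distinguishing geometry problems
from statistical degeneracies.
"""


class CTIQError(Exception):
    """Base class for all ctiq errors."""


class GeometryError(CTIQError, ValueError):
    """A phantom, insert or ROI does not fit where it was asked to go."""


class DetectionError(CTIQError, RuntimeError):
    """An image feature (e.g. a contrast insert) could not be located."""


class DegenerateDataError(CTIQError, ValueError):
    """Input data carry no information for the requested statistic
    (e.g. identical paired samples, all-zero rank differences)."""


class TooFewROIsError(CTIQError, ValueError):
    """The region admits fewer ROIs than the estimator needs."""


class NormalizationError(CTIQError, ValueError):
    """A curve cannot be normalized (zero area / zero DC component)."""
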