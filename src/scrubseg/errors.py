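"""Exception hierarchy for the toolkit.

Every error raised on purpose by scrubseg derives from :class:`ScrubsegError`,
so callers (and the CLI) can distinguish data problems from genuine bugs.
"""


class ScrubsegError(Exception):
    """Base class for all toolkit errors."""


class DimensionError(ScrubsegError):
    """Grids or arrays whose shapes do not line up."""


class GeometryError(ScrubsegError):
    """Invalid polygon geometry (self-intersection, zero area, ...)."""


class FormatError(ScrubsegError):
    """A file does not follow the expected dialect."""


class BoundsError(ScrubsegError):
    """Pixel coordinates outside the image grid."""


class MetricError(ScrubsegError):
    """A metric is undefined for the given inputs (e.g. no references)."""


class FusionError(ScrubsegError):
    """Fusion cannot proceed (e.g. an empty input segmentation)."""


class SpecError(ScrubsegError):
    """An invalid parameter/sweep/scene specification."""


class DataError(ScrubsegError):
    """Non-finite or otherwise unusable pixel data."""
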