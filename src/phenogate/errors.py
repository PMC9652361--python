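"""Exception hierarchy shared across the pipeline stages."""


class PhenogateError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(PhenogateError, ValueError):
    """A generator or analysis parameter is invalid or infeasible."""


class FormatError(PhenogateError, ValueError):
    """An input file does not match the expected layout (missing channel, shape mismatch)."""


class SegmentationError(PhenogateError):
    """Segmentation produced an empty or inconsistent mask; the message names the channel."""


class ThresholdError(PhenogateError):
    """Automatic thresholding is undefined (e.g. constant intensities in the ROI)."""


class GeometryError(PhenogateError, ValueError):
    """Degenerate geometry: duplicated vertices, out-of-range angles, non-positive lengths."""


class StatisticsError(PhenogateError, ValueError):
    """A test statistic is undefined for the given data (zero marginal, zero variance)."""
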