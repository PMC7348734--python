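"""Exception hierarchy for the lacpi pipeline.

Every error raised by the package derives from :class:`LacpiError` so callers
(and the CLI, which maps error classes onto exit codes) can distinguish
pipeline failures from programming errors.
"""


class LacpiError(Exception):
    """Base class for all lacpi errors."""


class FormatError(LacpiError):
    """Input image is not a grayscale integer stack this pipeline can use."""


class BitDepthError(FormatError):
    """Pixel values exceed the full scale implied by the declared bit depth."""


class LayoutError(LacpiError):
    """Surface layout is invalid or an ROI falls outside the frame bounds."""


class PairingError(LacpiError):
    """Sample/reference or baseline/follow-up summaries cannot be paired."""


class ScaleError(LacpiError):
    """Quantities measured on different full-scale values were combined."""


class RangeError(LacpiError):
    """A value lies outside its documented admissible range."""


class WindowError(LacpiError):
    """A requested analysis window is not covered by the series support."""


class UndefinedStatisticError(LacpiError):
    """A statistic (correlation, CV) is undefined for the given data."""


class InputError(LacpiError):
    """Structurally invalid or insufficient input for an operation."""
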