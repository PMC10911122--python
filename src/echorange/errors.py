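"""Exception hierarchy for echorange.

All domain errors derive from :class:`EchorangeError` so callers can catch
one base class at pipeline boundaries.
"""


class EchorangeError(Exception):
    """Base class for all echorange domain errors."""


class UnsupportedFormatError(EchorangeError):
    """Raster input is not 8-bit per channel or has an unsupported layout."""


class DegenerateImageError(EchorangeError):
    """Image has a single intensity value; min-max normalization is undefined."""


class EmptyMaskError(EchorangeError):
    """ROI rasterization selected no pixel, or a statistic was requested on one."""


class DimensionMismatchError(EchorangeError):
    """Image and mask (or paired vectors) differ in shape/length."""


class UndefinedCorrelationError(EchorangeError):
    """Pearson correlation requested on a zero-variance or too-short vector."""


class DegenerateTestError(EchorangeError):
    """Two-sample t-test with zero pooled variance."""


class NoAdmissibleRangeError(EchorangeError):
    """No intensity range satisfies the admissibility constraints."""


class InfeasibleParamsError(EchorangeError):
    """Synthetic-cohort parameters cannot produce the requested planted signal."""
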