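"""Exception hierarchy shared across the toolkit."""


class CropDepthError(Exception):
    """Base class for all toolkit-specific errors."""


class FormatError(CropDepthError, ValueError):
    """An on-disk artifact violates the expected value conventions."""


class DimensionError(CropDepthError, ValueError):
    """Array shapes disagree where they must match."""


class ParameterError(CropDepthError, ValueError):
    """A parameter violates its documented invariant."""


class DegenerateHistogramError(CropDepthError, ValueError):
    """Histogram has a single populated intensity; no split exists."""


class NoGradientError(CropDepthError, ValueError):
    """Gradient map is identically zero; gradient levels are undefined."""


class NoEdgesError(CropDepthError, ValueError):
    """Edge map is empty; edge-conditioned weights are undefined."""


class FitFailureError(CropDepthError, RuntimeError):
    """Sigmoid fit failed after all restarts."""
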