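"""Exception hierarchy shared across the package."""


class CyanorhythmError(Exception):
    """Base class for all package-specific errors."""


class GridError(CyanorhythmError):
    """Time grid is missing, non-uniform, or too short."""


class ShapeError(CyanorhythmError):
    """Array lengths or well/time shapes are inconsistent."""


class ParseError(CyanorhythmError):
    """Input file could not be parsed (missing columns, non-numeric values)."""


class ParamError(CyanorhythmError):
    """Invalid simulation parameters."""


class SpecError(CyanorhythmError):
    """Invalid experiment specification (e.g. duplicate well ids)."""


class FitError(CyanorhythmError):
    """Regression failed (too few points, rank-deficient design, no converged start)."""

    def __init__(self, msg, best_attempt=None):
        super().__init__(msg)
        self.best_attempt = best_attempt


class FeatureError(CyanorhythmError):
    """A required rhythm feature (trough/peak) could not be detected."""


class SampleError(CyanorhythmError):
    """Statistical sample too small for the requested test."""


class DomainError(CyanorhythmError):
    """Value outside the mathematical domain of the operation."""


class ConfigError(CyanorhythmError):
    """Invalid run configuration."""
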