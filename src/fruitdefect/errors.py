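"""Exception types shared across the package."""


class FruitDefectError(ValueError):
    """Base class for all package-specific errors."""


class ParameterError(FruitDefectError):
    """A scene or spec parameter violates its documented invariants."""


class ConfigError(FruitDefectError):
    """Invalid pipeline or tiling configuration."""


class ExtentMismatchError(FruitDefectError):
    """Two arrays that must share an extent do not."""


class DegenerateHistogramError(FruitDefectError):
    """A histogram has no separable gray-level classes (e.g. one gray level)."""


class WeightError(FruitDefectError):
    """Fusion weights violate alpha > beta >= 0."""
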