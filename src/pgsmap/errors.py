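"""Exception types shared across the pipeline."""


class PgsMapError(Exception):
    """Base class for all handled errors."""


class ConfigError(PgsMapError):
    """Invalid configuration value."""


class InvalidRegionError(PgsMapError):
    """Study region polygon is degenerate (zero area) or malformed."""


class EmptyGridError(PgsMapError):
    """Grid construction produced no nodes (spacing exceeds region extent)."""


class EmptyScoreError(PgsMapError):
    """No SNP passed the p-value threshold."""


class ZeroVarianceError(PgsMapError):
    """An input vector is constant where variation is required."""


class DimensionError(PgsMapError):
    """Input lengths do not agree."""


class SingularDesignError(PgsMapError):
    """Regression design matrix is rank deficient."""


class DegenerateWeightsError(PgsMapError):
    """Spatial weight matrix is all zero."""


class EmptyMapError(PgsMapError):
    """Every node failed to fit."""


class AlignmentError(PgsMapError):
    """Two map tables could not be aligned on the grid node index."""


class TransformError(PgsMapError):
    """A value transform was applied to values outside its domain."""
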