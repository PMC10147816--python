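"""Exception types raised across the pipeline."""


class DogconnError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(DogconnError):
    """Inconsistent generator or pipeline configuration."""


class StationarityError(ConfigurationError):
    """AR(1) coefficient outside the stationary region [0, 1)."""


class AlignmentError(DogconnError):
    """Inputs that must share an ROI order / universe do not."""


class SingularMatrixError(DogconnError):
    """Regressor matrix is rank deficient; semi-partial correlations undefined."""


class InsufficientDataError(DogconnError):
    """Too few time points, subjects or bilateral pairs for the requested statistic."""


class DegenerateGraphError(DogconnError):
    """Graph too small or too sparse for the requested metric."""
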