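"""Exception hierarchy shared across the package."""


class ColonyError(Exception):
    """Base class for all batcolony errors."""


class FormatError(ColonyError):
    """A file does not conform to the documented CSV dialect."""


class ValidationError(ColonyError):
    """A loaded or constructed object violates an invariant."""


class ConfigError(ColonyError):
    """Invalid configuration or simulation parameters."""


class DataError(ColonyError):
    """Input data reference something that does not exist."""


class FitError(ColonyError):
    """A model fit failed (non-convergence or degenerate covariate)."""


class DegenerateCovariateError(FitError):
    """A covariate column has no variance; the offending variable is named."""


class InsufficientSampleError(ColonyError):
    """Too few observations for the requested statistic."""
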