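"""Exception hierarchy for the tespipe pipeline.

Every stage raises a subclass of :class:`TesError` so callers (and the CLI)
can distinguish pipeline failures from programming errors.
"""


class TesError(Exception):
    """Base class for all tespipe errors."""


class FormatError(TesError):
    """A parsed input file violates its declared format."""


class ConfigurationError(TesError):
    """Invalid parameter values or an inconsistent configuration."""


class GenerationError(TesError):
    """The synthetic-data generator could not satisfy its contract."""


class ThresholdError(TesError):
    """A confidence threshold removed every edge from the network."""


class ConvergenceError(TesError):
    """An iterative solver failed to reach its tolerance."""


class NormalizationError(TesError):
    """Degenerate score range: normalization is undefined."""


class DegenerateCovariateError(TesError):
    """A covariate with zero variance cannot enter a regression."""


class FilterError(TesError):
    """The prognostic filter retained zero gene sets."""


class ClusteringError(TesError):
    """Clustering input is degenerate (e.g. zero-variance features)."""


class SchemaError(TesError):
    """Feature names of new data do not match the trained model."""


class PipelineError(TesError):
    """A pipeline stage failed; the message names the stage."""
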