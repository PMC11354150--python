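"""Exception hierarchy shared across the package."""


class CcprsError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CcprsError):
    """A file does not conform to the expected layout (columns, field counts)."""


class DataError(CcprsError):
    """A value inside an otherwise well-formed file is invalid."""


class ConfigError(CcprsError):
    """An analysis or simulation configuration is inconsistent."""


class EstimationError(CcprsError):
    """An estimator cannot be run on the given data (e.g. no complete rows)."""


class UndefinedStatisticError(CcprsError):
    """The requested statistic is undefined for the given input
    (zero margin odds ratio, zero-count allele frequency, zero pooled variance)."""


class SimulationError(CcprsError):
    """Synthetic-cohort generation failed (e.g. acceptance rate too low)."""


class PipelineError(CcprsError):
    """A pipeline stage failed; the message names the stage."""


class SeparationWarning(UserWarning):
    """Logistic fit showed complete or quasi-complete separation."""
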