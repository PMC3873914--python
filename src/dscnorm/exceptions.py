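"""Exception hierarchy for dscnorm."""


class DscnormError(Exception):
    """Base class for all dscnorm errors."""


class ParameterError(DscnormError, ValueError):
    """A model or acquisition parameter is out of its valid domain."""


class ConfigurationError(DscnormError, ValueError):
    """A cohort spec, region mapping or run config is inconsistent."""


class AIFDetectionError(DscnormError, RuntimeError):
    """Automatic arterial-input-function detection found no usable voxels."""


class DeconvolutionError(DscnormError, RuntimeError):
    """The deconvolution system is degenerate (e.g. all-zero AIF)."""


class AnalysisError(DscnormError, ValueError):
    """Group-statistics input does not meet the design requirements."""
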