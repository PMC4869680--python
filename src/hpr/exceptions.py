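"""Exception hierarchy for the hpr package.

All package errors derive from :class:`HprError` so callers can catch
pipeline failures with a single except clause while still discriminating
stages by subclass.
"""


class HprError(Exception):
    """Base class for all hpr errors."""


class UnsupportedRateError(HprError):
    """Sampling rate too low for the requested detector."""


class NoBeatsError(HprError):
    """No heartbeats could be identified in the waveform."""


class TemplateFailureError(HprError):
    """Too few template-eligible pulse peaks to build a matching template."""


class QualityError(HprError):
    """Data quality insufficient for automatic correction (e.g. >50% flagged)."""


class InsufficientDataError(HprError):
    """Not enough beats/subjects/trials for the requested operation."""


class InvalidSpecError(HprError):
    """Invalid filter specification (e.g. cutoff at or above Nyquist)."""


class InvalidParamsError(HprError):
    """Response-function parameters violate their constraints."""


class FitError(HprError):
    """Nonlinear fit failed to converge or input was degenerate."""


class IllPosedError(HprError):
    """Deconvolution/estimation problem is ill-posed (e.g. zero prior RF)."""


class MissingConditionError(HprError):
    """A required trial condition has no retained trials."""


class ValidationError(HprError):
    """Input file or table failed validation."""


class ConfigError(HprError):
    """Invalid simulation or pipeline configuration."""


class PipelineError(HprError):
    """Failure inside a composed pipeline run; message is stage-labelled."""
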