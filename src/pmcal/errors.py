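"""Exception hierarchy for the calibration pipeline.

Every error raised deliberately by pmcal derives from :class:`PmcalError`,
so callers (and the CLI) can distinguish pipeline failures from bugs.
"""


class PmcalError(Exception):
    """Base class for all pmcal errors."""


class ConfigurationError(PmcalError):
    """A column map, config file or model request is inconsistent."""


class EmptyInputError(PmcalError):
    """An operation received an empty observation set / pair set."""


class EmptyTrainingSetError(PmcalError):
    """Distance filtering removed every collocated pair."""


class AlignmentError(PmcalError):
    """Two per-record sequences that must align one-to-one do not."""


class SingularFitError(PmcalError):
    """The (global) regression design matrix is rank deficient."""


class UnderdeterminedFitError(PmcalError):
    """A local weighted fit has fewer effective points than coefficients."""


class BandwidthSelectionError(PmcalError):
    """No candidate bandwidth produced a usable set of local fits."""


class UndefinedCorrelationError(PmcalError):
    """Pearson correlation requested for a zero-variance series."""


class ScenarioValidationError(PmcalError):
    """A synthetic scenario's parameters are physically inconsistent."""
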