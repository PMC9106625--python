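"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`MetabodcvError` so drivers can
distinguish configuration mistakes from degenerate data.
"""


class MetabodcvError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MetabodcvError):
    """An invalid parameter value; the message names the offending field."""


class MetadataError(MetabodcvError):
    """Required sample metadata (batch, injection order, ...) is missing."""


class PreconditionError(MetabodcvError):
    """An operation's input contract is violated (e.g. no blank samples)."""


class SchemaError(MetabodcvError):
    """A file or matrix does not have the expected columns/variables."""


class AlignmentError(MetabodcvError):
    """Sample sets of two tables cannot be aligned."""


class PairingError(MetabodcvError):
    """A subject lacks the baseline/week-8 sample pair."""


class ComplexityError(MetabodcvError):
    """Requested latent-variable count exceeds what the data support."""


class CVError(MetabodcvError):
    """Cross-validation cannot be set up (too few samples per fold/arm)."""


class StratificationError(CVError):
    """An arm has too few subjects for a stratified split."""


class DegeneracyError(MetabodcvError):
    """Too few subjects/variables for the requested decomposition."""


class CalibrationError(MetabodcvError):
    """Retention-time calibration design is rank deficient or too small."""


class EstimationError(MetabodcvError):
    """A model fit failed due to degenerate variance."""
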