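"""Exception hierarchy shared across the package."""


class LfpDecodeError(Exception):
    """Base class for all package errors."""


class FormatError(LfpDecodeError):
    """An on-disk container is missing a required dataset or attribute."""


class ValidationError(LfpDecodeError):
    """An in-memory object violates its invariants."""


class ConfigurationError(LfpDecodeError):
    """A parameter combination is unusable (e.g. band invalid for fs)."""


class EstimationError(LfpDecodeError):
    """A statistical estimate cannot be formed (too few trials, singular matrix)."""


class TrainingError(LfpDecodeError):
    """Classifier training failed (e.g. a class with too few trials)."""
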