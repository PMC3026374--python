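"""Named exceptions raised across the package."""


class NsdbnError(Exception):
    """Base class for all package errors."""


class MissingDataError(NsdbnError):
    """A gene row cannot be imputed (e.g. entirely missing)."""


class DiscretizationError(NsdbnError):
    """Fold-change discretization is undefined (e.g. nonpositive gene mean)."""


class DetectionError(NsdbnError):
    """Regulator detection received an invalid threshold grid or window width."""


class InvalidStateError(NsdbnError):
    """A sampler state violates its structural invariants."""


class ScoringError(NsdbnError):
    """A score term cannot be evaluated (empty segment, bad hyperparameter)."""


class ConfigError(NsdbnError):
    """An invalid run configuration was supplied."""


class EvaluationError(NsdbnError):
    """ROC evaluation is undefined (empty trace, no positives or negatives)."""
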