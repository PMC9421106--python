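"""Exception hierarchy."""


class MalnowcastError(Exception):
    """Base class for package errors."""


class ConfigError(MalnowcastError, ValueError):
    """Invalid configuration value."""


class ReferenceRangeError(MalnowcastError, ValueError):
    """Measurement outside the growth-reference table's tabulated range."""


class UnclassifiableError(MalnowcastError, ValueError):
    """Child cannot be classified: basis measurement absent and no oedema."""


class EstimationError(MalnowcastError, RuntimeError):
    """Design-based estimation impossible (e.g. all records excluded)."""


class SplitError(MalnowcastError, ValueError):
    """Chronological train/holdout split impossible."""


class SelectionError(MalnowcastError, RuntimeError):
    """No estimable candidate in predictor-form selection."""


class ShortlistError(MalnowcastError, RuntimeError):
    """Shortlisting impossible (no holdout overlap)."""


class EvaluationError(MalnowcastError, RuntimeError):
    """Metric evaluation impossible (e.g. zero matched pairs)."""


class ImputationError(MalnowcastError, RuntimeError):
    """Series/panel imputation preconditions not met."""
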