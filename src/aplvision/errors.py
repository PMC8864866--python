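"""Exception hierarchy shared across pipeline stages."""


class AplVisionError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(AplVisionError, ValueError):
    """A cohort/cell-type specification violates its invariants."""


class InvalidConfigError(AplVisionError, ValueError):
    """A model or pipeline configuration violates its invariants."""


class InvalidParameterError(AplVisionError, ValueError):
    """An operation parameter is outside its allowed range."""


class DataError(AplVisionError, ValueError):
    """Input data unusable for the requested operation (empty set, single class...)."""


class StateError(AplVisionError, RuntimeError):
    """Operation requested on a model in the wrong state (e.g. untrained)."""


class FormatError(AplVisionError, ValueError):
    """A file could not be parsed in the expected dialect."""


class NoCellsError(DataError):
    """An image yielded zero analyzable cells; no smear-level call is possible."""


class UndefinedMetricError(AplVisionError, ValueError):
    """A metric is undefined for the given inputs (e.g. single-class labels)."""
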