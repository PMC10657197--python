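"""Exception hierarchy shared across the package."""


class SprayEvalError(Exception):
    """Base class for all package errors."""


class ValidationError(SprayEvalError, ValueError):
    """Malformed input data (boxes, records, parameters)."""


class ConfigurationError(SprayEvalError, ValueError):
    """Invalid nozzle or run configuration (e.g. n > image height)."""


class UndefinedMetricError(SprayEvalError, ZeroDivisionError):
    """A metric whose denominator is empty (e.g. WCR with zero GT weeds)."""


class AlignmentError(SprayEvalError, ValueError):
    """Mismatched image sets between per-image results and records."""
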