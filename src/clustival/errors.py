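"""Typed exceptions shared across the metric families."""


class ClustivalError(Exception):
    """Base class for all package errors."""


class InputError(ClustivalError, ValueError):
    """Raised when an input violates a precondition (shape, alignment, values)."""


class UndefinedMetricError(ClustivalError, ValueError):
    """Raised when a metric is mathematically undefined for the given input.

    Examples: Rand index with fewer than two elements, Wallace homogeneity
    of an all-singleton partition, separation of a single cluster.  Metrics
    raise this instead of silently returning NaN.
    """
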