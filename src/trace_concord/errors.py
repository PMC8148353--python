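"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: :class:`InputError` -> 2,
:class:`MetricError` -> 3. :class:`FitError` is recoverable inside the
pipeline (the raw tracing is kept and the record flagged).
"""


class TraceConcordError(Exception):
    """Base class for package errors."""


class InputError(TraceConcordError, ValueError):
    """Invalid or unusable input (bad file, empty mask, degenerate polygon)."""


class FitError(TraceConcordError, RuntimeError):
    """The direct ellipse fit failed (degenerate points, no ellipse solution)."""


class MetricError(TraceConcordError, RuntimeError):
    """A metric could not be computed (e.g. no usable ray directions)."""
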