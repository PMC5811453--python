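"""Exception hierarchy for the pipeline.

The CLI maps :class:`InputError` (and subclasses) to exit code 2 and
:class:`NumericalError` (and subclasses) to exit code 3.
"""


class AfmoscError(Exception):
    """Base class for all package errors."""


class InputError(AfmoscError):
    """Invalid input data or file (exit code 2)."""


class ParseError(InputError):
    """A delimited-text file could not be parsed; names the offending line."""


class ParameterError(InputError):
    """An argument is outside its documented domain."""


class SegmentError(InputError):
    """A force-curve operation received the wrong curve segment."""


class NumericalError(AfmoscError):
    """A numerical procedure failed (exit code 3)."""


class DegenerateSeriesError(NumericalError):
    """Residual variance is zero: standardization is undefined."""


class FitError(NumericalError):
    """A nonlinear fit failed to converge or returned a non-physical value."""
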