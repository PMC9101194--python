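"""Exception hierarchy.

Errors map onto CLI exit codes: input/parse problems exit 2, numerical
problems exit 3 (see :mod:`pffuzzy.cli`).
"""


class PffuzzyError(Exception):
    """Base class for all package errors."""


class InvalidSampleError(PffuzzyError):
    """Raised when raw measurements cannot form a valid sample (n < 2,
    non-finite values)."""


class DegenerateSampleError(PffuzzyError):
    """Raised when the sample standard deviation is zero, so the index
    estimate is undefined."""


class ParameterError(PffuzzyError):
    """Raised for invalid configuration values (alpha outside (0,1),
    n < 2, sigma <= 0, bad thresholds)."""


class DegenerateFuzzyNumberError(PffuzzyError):
    """Raised when the fuzzy number's base d_T = PF_R - PF_M is not
    positive, so the d_R/d_T ratio is undefined."""


class NumericalError(PffuzzyError):
    """Raised when a numerical routine (root finding) fails to converge;
    carries diagnostics rather than returning a silent wrong value."""


class ParseError(PffuzzyError):
    """Raised for malformed input files; the message names the file and,
    where applicable, the offending line number."""
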