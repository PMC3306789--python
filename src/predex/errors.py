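"""Exception hierarchy shared by all predex modules.

Validation problems (malformed input, bad configuration) and numerical
degeneracies (zero variance, undefined predictive variance) are kept
distinct so the command-line layer can map them to different exit codes.
"""


class PredexError(Exception):
    """Base class for all predex errors."""


class ValidationError(PredexError, ValueError):
    """Malformed input data or configuration."""


class DegenerateDataError(PredexError, ArithmeticError):
    """Data degenerate for the requested computation (e.g. zero range or
    zero variance where a positive scale is required)."""


class InsufficientDataError(PredexError, ValueError):
    """Fewer observations than the computation needs."""
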