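"""Exception hierarchy.

``ValidationError`` covers bad user input (parameters, lesion tables);
``NumericError`` covers solver/quadrature failures. The CLI maps them to
exit codes 2 and 3 respectively.
"""


class MbrplanError(Exception):
    """Base class for all package errors."""


class ValidationError(MbrplanError, ValueError):
    """Invalid parameter or input data."""


class NumericError(MbrplanError, ArithmeticError):
    """A numerical routine failed to converge or produced a non-finite result."""
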