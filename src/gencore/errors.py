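"""Exception hierarchy.

Validation problems (bad files, inconsistent networks, out-of-range
parameters) and numerical failures (non-finite data, degenerate
decompositions) are kept distinct so the command line can map them to
different exit codes.
"""


class GencoreError(Exception):
    """Base class for all package errors."""


class ValidationError(GencoreError):
    """Invalid input: malformed file, inconsistent network, bad parameter."""


class NumericalError(GencoreError):
    """Numerical failure: non-finite values, undefined decomposition."""
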