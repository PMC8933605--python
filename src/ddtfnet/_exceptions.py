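"""Exception hierarchy shared across the package.

``ValidationError`` covers malformed inputs and configuration; the numeric
subclasses signal failures of the estimation itself so callers (and the CLI)
can distinguish "your input is wrong" from "the computation broke down".
"""


class DDTFError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(DDTFError, ValueError):
    """Invalid input data, indices, labels or configuration."""


class DegenerateInputError(DDTFError, ValueError):
    """Structurally valid input on which the operation is undefined
    (e.g. an all-zero row handed to a row normalization)."""


class NumericalError(DDTFError, RuntimeError):
    """A numerical computation failed (rank deficiency, non-finite result)."""


class NearSingularError(NumericalError):
    """Spectral coefficient matrix too ill-conditioned to invert."""


class StabilityError(DDTFError, ValueError):
    """Autoregressive coefficients define an unstable (explosive) process."""
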