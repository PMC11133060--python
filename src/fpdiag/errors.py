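"""Exception hierarchy.

``FpdiagError`` is the common base so callers can catch everything from this
package with one clause; the CLI maps validation errors to exit code 2 and
computation failures to exit code 3.
"""


class FpdiagError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(FpdiagError, ValueError):
    """Invalid input data or parameters (CLI exit code 2)."""


class SchemaError(ValidationError):
    """A required column is missing or unparseable in an input table."""


class DegenerateInputError(ValidationError):
    """Input is formally valid but statistically degenerate (e.g. zero variance)."""


class ComputationError(FpdiagError, RuntimeError):
    """A pipeline stage failed during computation (CLI exit code 3)."""


class ResamplingError(ComputationError):
    """A resampling pool was empty or too small for the requested draw."""


class NoCrossingError(ComputationError):
    """Two estimated densities never cross within the evaluation grid."""
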