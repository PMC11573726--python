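"""Exception hierarchy.

Validation-type errors (bad input files, bad configuration) are distinguished
from runtime errors (e.g. a sampler that failed to converge) so the command
line interface can map them to distinct exit codes.
"""


class TrophisoError(Exception):
    """Base class for all package errors."""


class ValidationFailure(TrophisoError):
    """Base class for input/configuration problems (CLI exit code 2)."""


class SchemaError(ValidationFailure):
    """A required column is missing or the file layout is wrong."""


class ParseError(ValidationFailure):
    """A cell could not be parsed; carries row context in the message."""


class ValidationError(ValidationFailure):
    """A parsed record violates a domain invariant."""


class BinAssignmentError(ValidationFailure):
    """An elevation falls outside every configured bin."""


class ConfigurationError(ValidationFailure):
    """Run configuration is inconsistent (unknown site, bad mapping, ...)."""


class InputError(ValidationFailure):
    """An operation was called with inputs outside its contract."""


class InsufficientBaselineError(ValidationFailure):
    """Fewer than two plant samples available for a requested baseline."""


class SplitError(TrophisoError):
    """A two-source split produced a group with fewer than two samples."""


class ConvergenceError(TrophisoError):
    """MCMC did not converge (some split-R-hat >= 1.1)."""
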