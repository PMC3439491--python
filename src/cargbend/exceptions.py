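"""Package-specific error types.

All inherit from :class:`CargBendError` so callers (and the CLI) can catch
validation problems with a single except clause.
"""


class CargBendError(ValueError):
    """Base class for all cargbend validation and fitting errors."""


class InvalidAlphabetError(CargBendError):
    """Sequence contains characters outside the allowed alphabet."""


class LengthError(CargBendError):
    """Sequence or window has the wrong length for the operation."""


class SchemaError(CargBendError):
    """Tabular input is missing a required column or has a malformed row."""


class InsufficientDataError(CargBendError):
    """Too few data points to constrain the model."""


class DegenerateFitError(CargBendError):
    """The fitted model is outside its physically meaningful domain."""


class UnidentifiableError(CargBendError):
    """The data cannot distinguish the model's parameters."""


class IndeterminatePhaseError(CargBendError):
    """Phase classification requested on a fit with zero amplitude."""
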