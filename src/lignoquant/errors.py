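"""Exception hierarchy shared by all pipeline stages."""


class LignoquantError(Exception):
    """Base class for all package-specific errors."""


class InvalidDesignError(LignoquantError, ValueError):
    """A generator or experiment design is internally inconsistent."""


class GridMismatchError(LignoquantError, ValueError):
    """Spectra that must share a wavenumber grid do not."""


class StageError(LignoquantError, ValueError):
    """A preprocessing operation was applied out of order."""


class DomainError(LignoquantError, ValueError):
    """Input values are outside the mathematical domain of an operation."""


class DegenerateInputError(LignoquantError, ValueError):
    """Input is degenerate (e.g. all-zero spectrum, zero-variance design)."""


class DegenerateFitError(LignoquantError, ValueError):
    """A least-squares fit produced an unusable solution."""


class ResampleRequiredError(LignoquantError, ValueError):
    """Operation requires a uniform grid; resample first."""


class ParameterError(LignoquantError, ValueError):
    """An operation parameter is invalid."""


class EmptyInputError(LignoquantError, ValueError):
    """An operation received an empty collection."""


class WindowError(LignoquantError, ValueError):
    """A peak window falls outside the spectral grid."""


class InsufficientDataError(LignoquantError, ValueError):
    """Too few observations to run a statistical comparison."""


class NonIdentifiableError(LignoquantError, ValueError):
    """Model parameters cannot be identified from the data."""


class ConsistencyError(LignoquantError, ValueError):
    """Tabulated counts are mutually inconsistent."""
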