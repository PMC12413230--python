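"""Exception hierarchy for multipletfit."""


class MultipletFitError(Exception):
    """Base class for all multipletfit errors."""


class DomainError(MultipletFitError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class ConfigurationError(MultipletFitError, ValueError):
    """A model/parameter configuration is incomplete or inconsistent."""


class ValidationError(MultipletFitError, ValueError):
    """A declarative definition violates an invariant; message names the field."""


class FormatError(MultipletFitError, ValueError):
    """An input file cannot be parsed; message locates the problem."""


class VersionError(FormatError):
    """A session file was written by a newer, unknown schema version."""


class InitializationError(MultipletFitError, ValueError):
    """Parameter initialization from a peak list is impossible."""


class FitError(MultipletFitError, RuntimeError):
    """The optimizer encountered a non-finite cost or an invalid state."""


class BatchError(MultipletFitError, RuntimeError):
    """The batch reference fit failed; nothing can be propagated."""


class GenerationError(MultipletFitError, ValueError):
    """A synthetic-data request produced invalid parameters."""
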