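"""Exception hierarchy for screen-analysis failures."""


class QhtsError(Exception):
    """Base class for all qhtscreen errors."""


class InvalidArgumentError(QhtsError, ValueError):
    """An argument violates a precondition (non-positive volume, factor <= 1, ...)."""


class InsufficientDataError(QhtsError):
    """Too few usable points for the requested operation (e.g. < 4 for a 4PL fit)."""


class DegenerateControlsError(QhtsError):
    """Control statistics cannot anchor a normalization (mu_neg == mu_pos)."""


class SchemaError(QhtsError):
    """A data file violates the expected long-format plate schema."""


class ConfigurationError(QhtsError):
    """A stack or config is structurally unusable (e.g. missing bracketing DMSO plates)."""


class LookupFailure(QhtsError, KeyError):
    """A referenced sample or compound is not present."""
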