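"""Exception hierarchy for the 2MST processing pipelines."""


class TwoMSTError(Exception):
    """Base class for all package errors."""


class FormatError(TwoMSTError):
    """A file does not match the declared dialect (missing columns, bad header)."""


class DataError(TwoMSTError):
    """The file parsed but its content violates a contract (non-monotone time, empty report)."""


class ParameterError(TwoMSTError):
    """An operation was configured outside its valid domain (e.g. cutoff >= Nyquist)."""


class InsufficientDataError(TwoMSTError):
    """Not enough samples/windows/pairs to perform the operation."""


class UndefinedFrequencyError(TwoMSTError):
    """Spectral content is empty after mean-centering (constant segment)."""


class GroupingError(TwoMSTError):
    """Subject-wise cross-validation is impossible (fewer than two subjects)."""


class LeakageError(TwoMSTError):
    """Test-partition data reached a fitting call, or a fitted artifact is being
    evaluated on cycles it was trained on."""


class SchemaError(TwoMSTError):
    """A feature table does not carry the columns a fitted model expects."""


class PairingError(TwoMSTError):
    """Two series meant to be compared pairwise cannot be paired."""


class ContractError(TwoMSTError):
    """A numerical precondition was violated (e.g. parabolic refinement off a maximum)."""
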