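"""Exception hierarchy used across the package."""


class SeqArchitectError(Exception):
    """Base class for all package errors."""


class InvalidInputError(SeqArchitectError, ValueError):
    """An argument violates a documented precondition."""


class BuildError(SeqArchitectError):
    """A hyperparameter configuration cannot be realized as a network plan."""


class InsufficientDataError(SeqArchitectError):
    """Too few observations to fit the requested model."""


class CannotFitError(SeqArchitectError):
    """No batch size, not even 1, passes the memory probe."""


class FastaParseError(SeqArchitectError):
    """A FASTA file is malformed; the message carries the offending line."""


class SequenceTooShortError(InvalidInputError):
    """A sequence is shorter than the requested window length."""
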