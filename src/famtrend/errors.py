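"""Exception hierarchy shared across the package."""


class FamtrendError(ValueError):
    """Base class for all data errors raised by famtrend."""


class ParseError(FamtrendError):
    """A file could not be parsed (bad character, empty input, ...)."""


class AlignmentShapeError(FamtrendError):
    """Alignment records do not all have the same length."""


class MissingIdError(FamtrendError):
    """A requested sequence id is not present in the family."""


class MissingChainError(FamtrendError):
    """A requested chain id is not present in the structure file."""


class LowIdentityError(FamtrendError):
    """Sequence-to-structure alignment identity fell below the threshold."""
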