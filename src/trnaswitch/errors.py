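"""Exception hierarchy shared across the package."""


class TrnaswitchError(Exception):
    """Base class for package errors."""


class InputError(TrnaswitchError, ValueError):
    """Malformed or out-of-range user input."""


class AlphabetError(InputError):
    """Sequence contains characters outside the expected alphabet."""


class FrameError(InputError):
    """Coding sequence length is not a multiple of three."""


class ValidationError(TrnaswitchError, ValueError):
    """A domain object violates one of its invariants."""
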