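"""Exception types shared across graintex modules."""


class GraintexError(Exception):
    """Base class for all graintex errors."""


class InvalidParameterError(GraintexError, ValueError):
    """A parameter is outside its admissible domain (e.g. sigma <= 0)."""


class ImageSizeError(GraintexError, ValueError):
    """An image (or subimage) is too small for the requested kernel support."""


class DegenerateInputError(GraintexError, ValueError):
    """Input carries no usable signal (e.g. constant samples, zero spread)."""


class LayoutMismatchError(GraintexError, ValueError):
    """A feature table's column layout does not match the expected config."""


class PackingError(GraintexError, RuntimeError):
    """Non-overlapping particle placement failed within the retry budget."""
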