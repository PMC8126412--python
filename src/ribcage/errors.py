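"""Exception hierarchy for the ribcage pipeline."""


class RibcageError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(RibcageError):
    """An input object violates one of its documented invariants."""


class FormatError(RibcageError):
    """A file does not conform to the expected interchange format."""


class IntegrityError(RibcageError):
    """A table violates a uniqueness or ordering constraint."""


class GeometryError(RibcageError):
    """A geometric precondition fails (degenerate extent, empty side, ...)."""
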