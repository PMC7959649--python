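"""Exception types shared across the package."""


class BlockArtError(Exception):
    """Base class for all package-specific errors."""


class DegenerateRayError(BlockArtError):
    """A ray has a zero-length chord through the domain (geometry bug)."""


class DegenerateRowError(BlockArtError):
    """A system-matrix row is identically zero; no projection is defined."""


class InvalidPhantomError(BlockArtError):
    """Phantom regions overlap in their interiors or leave the domain."""


class ParseError(BlockArtError):
    """A file could not be parsed.

    Parameters
    ----------
    message : str
    line : int, optional
        1-based line number where parsing failed, when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class NoConvergenceError(BlockArtError):
    """Every cell of a sweep was censored; no optimum can be reported."""
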