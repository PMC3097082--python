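"""Exception types shared across the package."""


class PhyloError(Exception):
    """Base class for all package errors."""


class NewickParseError(PhyloError, ValueError):
    """Malformed newick input.

    Carries ``offset`` (0-based character position, when known) so callers
    can point at the offending token.
    """

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (near character {offset})"
        super().__init__(message)


class ValidationError(PhyloError, ValueError):
    """Structurally invalid input (duplicate taxa, bad ranges, ...)."""
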