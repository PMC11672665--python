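"""Exception hierarchy shared across the package."""


class DhaspecError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(DhaspecError):
    """Invalid user input: bad files, mismatched dimensions, bad parameters."""


class NumericalError(DhaspecError):
    """A numerical evaluation produced non-finite or undefined results."""


class UnsupportedElementError(ValidationError):
    """Element symbol not present in the embedded mass table."""

    def __init__(self, symbol: str):
        self.symbol = symbol
        super().__init__(f"unsupported element symbol: {symbol!r}")


class UndefinedScoreError(NumericalError):
    """A similarity score is undefined for the given inputs (e.g. all-zero spectrum)."""
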