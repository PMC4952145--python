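"""Exception hierarchy for the posdev pipeline."""


class PosdevError(Exception):
    """Base class for all posdev errors."""


class SchemaError(PosdevError):
    """A declared column is missing or the role map is inconsistent."""


class IntegrityError(PosdevError):
    """Duplicate keys or conflicting records in a panel or result set."""


class ParseError(PosdevError):
    """A cell could not be parsed; carries row/column coordinates."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        super().__init__(message)
        self.row = row
        self.column = column


class CategoryError(PosdevError):
    """A categorical cell holds a value outside its declared category set."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        super().__init__(message)
        self.row = row
        self.column = column


class ConfigError(PosdevError):
    """Invalid simulation or pipeline configuration."""


class UnderdeterminedFitError(PosdevError):
    """n <= number of design columns: the least-squares fit is underdetermined."""


class InsufficientDFError(PosdevError):
    """Not enough residual degrees of freedom for external studentization."""


class NestingError(PosdevError):
    """Models passed to the likelihood-ratio test are not properly nested."""


class DegenerateCellError(PosdevError):
    """A (state, outcome, year) cell cannot be analysed (e.g. constant outcome)."""
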