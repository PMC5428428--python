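"""Exception hierarchy shared across the package."""


class GlyhomeError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(GlyhomeError):
    """An input table is missing mandatory columns or has a malformed header."""


class IntegrityError(GlyhomeError):
    """Duplicate keys or otherwise inconsistent records in an input table."""


class ParseError(GlyhomeError):
    """A row holds a value that cannot be parsed; carries the row index."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class UnresolvedGIError(GlyhomeError):
    """No assignment tier could resolve a glycemic index for a food."""


class UndefinedGIError(GlyhomeError):
    """A GI is requested for a food set with zero total carbohydrate."""


class LookupFoodError(GlyhomeError):
    """A recall record references a food absent from the food table."""


class CalibrationError(GlyhomeError):
    """Generator calibration targets are infeasible."""


class DegenerateModifierError(GlyhomeError):
    """An interaction modifier is constant and carries no information."""


class ConsistencyError(GlyhomeError):
    """Component quantities violate an accounting identity (e.g. energies)."""
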