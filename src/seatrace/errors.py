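"""Exception hierarchy.

Every data problem raises a subclass of :class:`SeatraceError` carrying
enough context (column, row, offending names) to fix the input.
"""

from __future__ import annotations


class SeatraceError(Exception):
    """Base class for all package errors."""


class SchemaError(SeatraceError):
    """An input table does not have the documented header/schema."""


class ValidationError(SeatraceError):
    """An input table violates a row-level invariant (negative quantity,
    duplicate key, unknown label, unparseable value...)."""


class UnmappedNameError(SeatraceError):
    """A reporter/partner raw name is absent from the harmonization table.

    Silent drops would bias import shares, so this is a hard error; the
    unmapped names are listed on ``.names``.
    """

    def __init__(self, names):
        self.names = tuple(sorted(set(names)))
        super().__init__(
            "raw name(s) missing from harmonization table: "
            + ", ".join(self.names)
        )


class UnmappedProductError(SeatraceError):
    """A product code has no ISSCAAP group mapping."""

    def __init__(self, codes):
        self.codes = tuple(sorted(set(codes)))
        super().__init__(
            "product code(s) without ISSCAAP group mapping: "
            + ", ".join(self.codes)
        )


class GapfillError(SeatraceError):
    """The gap-filling regression cannot be fitted or applied
    (rank deficiency, unseen region, missing SPI, unresolvable country)."""


class MissingCompositionError(SeatraceError):
    """A trade partner with a positive import share has no production/import
    composition (no balance entry and no group membership to average over)."""

    def __init__(self, partners):
        self.partners = tuple(sorted(set(partners)))
        super().__init__(
            "no export composition available for partner(s): "
            + ", ".join(self.partners)
        )


class ConfigError(SeatraceError):
    """An analysis or world configuration is invalid or infeasible."""
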