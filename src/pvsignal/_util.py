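"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at `ndigits` decimals.

    Python's built-in ``round`` is banker's rounding; report tables in
    pharmacovigilance are conventionally printed with half-up rounding
    (0.125 -> 0.13 at 2 dp), so percentages and statistics are formatted
    through this helper.
    """
    if x != x:  # NaN passes through
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


class PvSignalError(Exception):
    """Base class for errors raised by this package."""


class SchemaError(PvSignalError):
    """An input file does not carry a mandatory column for its layout."""


class ConfigurationError(PvSignalError):
    """Invalid user-supplied configuration."""


class UndefinedResultError(PvSignalError):
    """A statistic is undefined for the given contingency table."""
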