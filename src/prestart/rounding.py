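"""Decimal rounding helpers (half away from zero, as in printed tables)."""

from decimal import Decimal, ROUND_HALF_UP


def round_half_away(value: float, ndigits: int) -> float:
    """Round with ties going away from zero (so 0.7965 -> 0.80 at 2 dp).

    Python's built-in ``round`` uses banker's rounding and binary floats;
    published clinical tables round half away from zero on the decimal
    representation, which this reproduces via ``Decimal``.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def percent(value: float, ndigits: int = 1) -> float:
    """Proportion -> percentage at the printed precision (1 dp default)."""
    return round_half_away(100.0 * value, ndigits)
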