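"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero (report-style rounding).

    Python's builtin ``round`` is banker's rounding; printed tables in this
    domain use half-up, so 1.725 -> 1.73 and 9.85 -> 9.9.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, total: int, ndigits: int = 1) -> float:
    """Percentage of ``count`` over ``total``, half-up at ``ndigits`` decimals."""
    if total == 0:
        return 0.0
    return round_half_up(100.0 * count / total, ndigits)
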