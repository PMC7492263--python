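"""Rounding and percentage helpers used by every reporting surface.

Percentages are rounded half-up (not banker's rounding) so printed values
match conventional manual reporting style.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Optional


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round ``x`` half-up to ``ndigits`` decimal places."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 2) -> Optional[float]:
    """100 * numerator / denominator, rounded half-up.

    Returns None for a zero denominator: an undefined fraction is reported as
    missing, never coerced to 0.
    """
    if denominator == 0:
        return None
    return round_half_up(100.0 * numerator / denominator, ndigits)
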