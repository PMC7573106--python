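"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int) -> float:
    """Round with ties away from zero, as printed percentages are.

    Plain ``round`` uses banker's rounding (100/32 -> 3.12); reported
    thresholds and redundancies expect 3.13-style half-up behaviour.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
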