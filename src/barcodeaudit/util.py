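"""Small shared helpers."""

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (2.25 -> 2.3 at 1 digit), unlike banker's
    rounding; applied only at serialization time."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
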