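"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (half-up), unlike banker's rounding.

    Used wherever a reported figure is rounded (consensus midpoints,
    expected counts, percentages), so that e.g. 0.5 -> 1 and 62.65 -> 62.7.
    """
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return float(d) if ndigits > 0 else float(int(d))
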