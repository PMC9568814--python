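"""Half-up decimal rounding shared by the reporting surfaces."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, decimals: int = 0) -> float:
    """Round with ties away from zero at the printed precision (not banker's)."""
    q = Decimal(1).scaleb(-decimals)
    rounded = Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP)
    return float(rounded) if decimals > 0 else int(rounded)
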