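"""Small shared helpers (rounding/percentage conventions)."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (0.005 -> 0.01), as printed tables do."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pct(count: float, total: float, ndigits: int = 2) -> float:
    """Percentage of ``count`` in ``total``, rounded half-up.

    Zero total yields 0.0 rather than an error so empty groups print as 0.
    """
    if total == 0:
        return 0.0
    return round_half_up(100.0 * count / total, ndigits)
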