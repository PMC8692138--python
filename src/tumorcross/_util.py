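"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (0.25 -> 0.3 at 1 digit).

    Python's built-in ``round`` uses banker's rounding; reported
    percentages and per-tumor means follow the half-up convention
    instead so printed tables are stable across platforms.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def derive_seed(seed: int, salt: int) -> int:
    """Derive a stream-specific 31-bit seed from a master seed."""
    return (seed * 1_000_003 + salt) % (2**31 - 1)
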