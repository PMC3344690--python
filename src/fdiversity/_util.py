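"""Small shared numeric/formatting helpers."""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "format_p_value", "P_VALUE_FLOOR"]

#: p-values below this are reported as "< 0.00001" in formatted output.
P_VALUE_FLOOR = 1e-5


def round_half_up(x: float, digits: int = 4) -> float:
    """Round with ties away from zero, as in the published tables.

    Python's built-in ``round`` uses banker's rounding; tables here follow
    the half-up convention (0.00005 -> 0.0001).
    """
    x = float(x)
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_p_value(p: float, floor: float = P_VALUE_FLOOR, digits: int = 5) -> str:
    """Fixed-decimal p-value string with a reporting floor.

    Values below ``floor`` are printed as ``"< 0.00001"`` rather than as a
    spuriously precise number.
    """
    if p < floor:
        return f"< {floor:.{digits}f}"
    return f"{round_half_up(p, digits):.{digits}f}"
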