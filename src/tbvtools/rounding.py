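"""Report-time rounding.

All internal quantities are carried at full floating precision; rounding is
applied only when a value is printed or tabulated.  The convention throughout
is *round half up* (0.5 always rounds away from zero toward the next larger
value), not Python's default banker's rounding: 12.5 -> 13, 12.44 -> 12.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "ceil_units"]


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round ``value`` to ``ndigits`` decimals, ties going up.

    Uses decimal arithmetic on the shortest repr of the float so that values
    that print as exact halves (e.g. 4.65 at one decimal) behave the way a
    person reading the printed number expects.  Returns a float; with
    ``ndigits=0`` the result is integral-valued.
    """
    value = float(value)  # accept numpy scalars
    if not math.isfinite(value):
        raise ValueError(f"cannot round non-finite value {value!r}")
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def ceil_units(value: float) -> int:
    """Ceiling used by the optional conservative unit-count mode."""
    return int(math.ceil(value - 1e-9))
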