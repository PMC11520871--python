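"""Half-up rounding helpers.

Python's builtin ``round`` is banker's rounding; projected person counts and
presentation percentages use conventional half-up instead.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float) -> int:
    """Round a non-negative float to the nearest integer, ties away from zero."""
    if x < 0:
        return -round_half_up(-x)
    return int(math.floor(x + 0.5))


def round_half_up_to(x: float, ndigits: int) -> float:
    """Round ``x`` to ``ndigits`` decimal places with half-up ties."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
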