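"""Rounding conventions for table reproduction."""

from __future__ import annotations

import math


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention of clinical tables).

    Python's built-in ``round`` uses banker's rounding, which disagrees with
    printed clinical tables on exact halves (e.g. 72.5 -> 72 instead of 73).
    """
    if math.isnan(x):
        return x
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)
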