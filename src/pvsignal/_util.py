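"""Small shared helpers."""

from __future__ import annotations

import math


def round1(x: float) -> float:
    """Round to one decimal, half away from zero.

    This is the rounding rule used for every reported percentage, chosen
    over banker's rounding so printed shares are reproducible exactly.
    """
    return math.copysign(math.floor(abs(x) * 10 + 0.5), x) / 10


def pct(count: int, total: int) -> float:
    """Percentage of ``count`` in ``total``, rounded with :func:`round1`."""
    if total == 0:
        raise ZeroDivisionError("percentage of an empty total")
    return round1(100.0 * count / total)
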