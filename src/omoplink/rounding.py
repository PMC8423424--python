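"""Decimal percentage arithmetic shared by the coverage and concordance reports.

Reported percentages are truncated (rounded toward zero) to the requested
number of decimal places by default; this is the rule that reproduces the
reference accounting tables. Banker's rounding is available as an option.
"""

from __future__ import annotations

from decimal import ROUND_DOWN, ROUND_HALF_EVEN, Decimal

MODES = {"truncate": ROUND_DOWN, "half-even": ROUND_HALF_EVEN}


def pct(count: int | float, denominator: int | float, places: int = 2,
        mode: str = "truncate") -> float:
    """100*count/denominator, quantized to *places* decimals.

    Exact decimal arithmetic, so e.g. ``pct(267925, 502367)`` is 53.33
    regardless of float representation.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    q = Decimal(1).scaleb(-places)
    value = (Decimal(count) * 100 / Decimal(denominator)).quantize(q, rounding=MODES[mode])
    return float(value)
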