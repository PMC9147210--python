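"""Percent formatting shared by every report-producing module.

Validation tables in clinical assay reports print percentages at two
decimal places with round-half-up (so 94.445 -> "94.45%", not banker's
rounding), and by convention never display an imperfect rate as 100.00%:
a specificity with a handful of false positives is shown as 99.99%, the
highest value short of perfection, because "100.00%" would overstate the
evidence. Raw fractions are always retained alongside the display string.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_percent", "format_percent", "NA"]

#: Sentinel string for undefined metrics (zero denominator).
NA = "NA"


def round_percent(fraction: float, *, cap_below_one: bool = True) -> float:
    """Convert a fraction in [0, 1] to a percent rounded half-up to 2 dp.

    Parameters
    ----------
    fraction
        Proportion on the 0-1 scale. NaN propagates.
    cap_below_one
        If True (default), a fraction strictly below 1 never rounds up to
        100.00; it is capped at 99.99. Exact 1.0 still yields 100.0.
    """
    if math.isnan(fraction):
        return float("nan")
    pct = Decimal(repr(fraction)) * 100
    out = float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
    if cap_below_one and fraction < 1 and out >= 100.0:
        out = 99.99
    return out


def format_percent(fraction: float | None, *, cap_below_one: bool = True) -> str:
    """Render a fraction as a 2-dp percent string, or ``"NA"`` if undefined."""
    if fraction is None or (isinstance(fraction, float) and math.isnan(fraction)):
        return NA
    return f"{round_percent(fraction, cap_below_one=cap_below_one):.2f}%"
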