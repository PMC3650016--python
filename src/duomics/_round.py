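"""Half-up decimal rounding for report-layer numbers.

Full precision is carried everywhere internally; rounding happens only when a
summary value is presented (percentages to 2 dp, activity ratios to 3 dp).
Python's built-in round() is banker's rounding, which disagrees with how the
summary tables round, hence this helper.
"""

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int) -> float:
    """Round *x* half-up to *ndigits* decimal places."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
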