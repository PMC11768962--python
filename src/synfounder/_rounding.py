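"""Decimal rendering of exact rationals.

Analytic modules work in :class:`fractions.Fraction`; decimals appear
only at presentation boundaries.  Rounding is half-away-from-zero, the
convention under which the reference tables reproduce digit for digit
(e.g. 0.9375 -> 0.94, 0.5833... -> 0.58).
"""

from __future__ import annotations

import decimal
from decimal import Decimal
from fractions import Fraction

__all__ = ["to_decimal", "round_half_away", "truncate"]

# enough headroom that quantizing 2-6 d.p. can never be perturbed;
# rational ties at d decimals always have denominator 2*10^d, hence are
# exactly representable in Decimal
_PREC = 60


def to_decimal(x: Fraction) -> Decimal:
    """Exact-or-near-exact Decimal image of a rational (60 digits)."""
    with decimal.localcontext() as ctx:
        ctx.prec = _PREC
        return Decimal(x.numerator) / Decimal(x.denominator)


def round_half_away(x: Fraction, ndigits: int) -> Decimal:
    """Round a rational to ``ndigits`` decimals, half away from zero."""
    q = Decimal(1).scaleb(-ndigits)
    with decimal.localcontext() as ctx:
        ctx.prec = _PREC
        return to_decimal(x).quantize(q, rounding=decimal.ROUND_HALF_UP)


def truncate(x: Fraction, ndigits: int) -> Decimal:
    """Truncate a rational toward zero at ``ndigits`` decimals."""
    q = Decimal(1).scaleb(-ndigits)
    with decimal.localcontext() as ctx:
        ctx.prec = _PREC
        return to_decimal(x).quantize(q, rounding=decimal.ROUND_DOWN)
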