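"""Numeric rendering in the style of printed transfer-frequency tables.

Derived quantities (TE/donor frequencies, relative mobilities) are kept as
exact rationals internally and rendered at three significant figures; cargo
capacity rates are rendered at two decimal places.  Both use half-up
rounding of the exact value, which is the convention the printed tables
follow (e.g. an exact 3.845e-4 prints as "3.85 × 10^−4").
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal, localcontext
from fractions import Fraction
from numbers import Rational

MULTIPLY_SIGN = "×"  # ×
MINUS_SIGN = "−"  # − (as printed in exponents)

ND = "ND"


def as_fraction(value: object) -> Fraction:
    """Convert a number or decimal string to an exact :class:`Fraction`.

    Strings and Decimals are parsed exactly ("6.0e-5" becomes 3/50000),
    which is what table transcription requires; floats go through their
    shortest decimal repr so that ``as_fraction(6.0e-5)`` round-trips to
    the intended decimal rather than the binary expansion.
    """
    if isinstance(value, Fraction):
        return value
    if isinstance(value, Rational):  # int and friends
        return Fraction(value)
    if isinstance(value, Decimal):
        return Fraction(value)
    if isinstance(value, float):
        return Fraction(Decimal(repr(value)))
    if isinstance(value, str):
        s = value.strip()
        if "/" in s:
            num, den = s.split("/", 1)
            return Fraction(Decimal(num.strip())) / Fraction(Decimal(den.strip()))
        return Fraction(Decimal(s))
    raise TypeError(f"cannot interpret {value!r} as an exact rational")


def round_sig(value: object, sig: int = 3) -> Decimal:
    """Round an exact rational to ``sig`` significant figures, half-up."""
    frac = as_fraction(value)
    if frac == 0:
        return Decimal(0)
    with localcontext() as ctx:
        ctx.prec = sig
        ctx.rounding = ROUND_HALF_UP
        # single correctly-rounded division of the exact value
        return Decimal(frac.numerator) / Decimal(frac.denominator)


def sci_notation(value: object, sig: int = 3) -> str:
    """Render like the tables do: "4.62 × 10^−1", or plain "2.46" for 10^0."""
    d = round_sig(value, sig)
    if d == 0:
        return "0"
    exponent = d.adjusted()
    mantissa = d.scaleb(-exponent).quantize(Decimal(1).scaleb(-(sig - 1)))
    if exponent == 0:
        return str(mantissa)
    exp_str = str(exponent).replace("-", MINUS_SIGN)
    return f"{mantissa} {MULTIPLY_SIGN} 10^{exp_str}"


def two_decimals(value: object) -> Decimal:
    """Round to two decimal places half-up (cargo capacity rate rendering)."""
    frac = as_fraction(value)
    with localcontext() as ctx:
        ctx.prec = 40
        ctx.rounding = ROUND_HALF_UP
        d = Decimal(frac.numerator) / Decimal(frac.denominator)
    return d.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)


def rate_string(value: object) -> str:
    return str(two_decimals(value))


def count_string(value: Fraction) -> str:
    """Render an ORF count: integers plain, half-units with one decimal."""
    frac = as_fraction(value)
    if frac.denominator == 1:
        return str(frac.numerator)
    return str(Decimal(frac.numerator) / Decimal(frac.denominator))


def parse_scientific(text: str) -> float:
    """Parse a printed value such as "3.05 × 10^−5", "2.46" or "1.57e8"."""
    s = text.strip().replace(MINUS_SIGN, "-").replace(MULTIPLY_SIGN, "x")
    if s in ("", ND, "-", "—"):
        raise ValueError(f"not a number: {text!r}")
    if "x" in s:
        mant, _, rest = s.partition("x")
        base = rest.strip()
        if not base.startswith("10^"):
            raise ValueError(f"unrecognised scientific notation: {text!r}")
        return float(mant.strip()) * 10.0 ** int(base[3:])
    return float(s)


def significant_value(value: object, sig: int = 3) -> float:
    """Float of the value rounded to ``sig`` significant figures."""
    return float(round_sig(value, sig))
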