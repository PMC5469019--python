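"""Decimal currency helpers.

Money is carried as :class:`decimal.Decimal` throughout the package and is
serialized as plain decimal text with two fractional digits.  Binary floats
never touch a fee, charge, or cost, so cent-level known-answer checks are
exact.  Rounding is half-away-from-zero (``ROUND_HALF_UP``), applied once at
the end of each line's computation.
"""

from __future__ import annotations

from decimal import Decimal, InvalidOperation, ROUND_HALF_UP

CENT = Decimal("0.01")
TENTH = Decimal("0.1")

ZERO = Decimal("0")


def D(value: object) -> Decimal:
    """Coerce to Decimal via str() so floats do not leak binary noise."""
    if isinstance(value, Decimal):
        return value
    return Decimal(str(value))


def round_cents(value: Decimal) -> Decimal:
    """Round to cents, ties away from zero."""
    return value.quantize(CENT, rounding=ROUND_HALF_UP)


def round_tenth(value: Decimal) -> Decimal:
    """Round to one decimal place, ties away from zero (anesthesia time units)."""
    return value.quantize(TENTH, rounding=ROUND_HALF_UP)


def fmt_money(value: Decimal) -> str:
    return str(round_cents(D(value)))


def parse_money(text: str) -> Decimal:
    try:
        return Decimal(text)
    except InvalidOperation as exc:  # pragma: no cover - message carrier
        raise ValueError(f"not a decimal amount: {text!r}") from exc


def sign(value: Decimal | int) -> int:
    if value > 0:
        return 1
    if value < 0:
        return -1
    return 0
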