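"""Outcome categories and coding shared across the package.

Both assessment methods rate a suspected adverse drug reaction into one of
four ordered causality categories (definite > probable > possible > unlikely)
or declare the case unassessable.  File formats encode these as integer codes
1..5 in that order, and the two methods as tool codes 1 (WHO-UMC) and 2 (LCAT).
"""

from __future__ import annotations

#: The five outcome labels, file-code order (codes 1..5).
CATEGORIES: tuple[str, ...] = (
    "definite",
    "probable",
    "possible",
    "unlikely",
    "unassessable",
)

#: The four ordinal categories (rank 1..4); "unassessable" carries no rank.
ORDINAL_CATEGORIES: tuple[str, ...] = CATEGORIES[:4]

ORDINAL_RANK: dict[str, int] = {c: i + 1 for i, c in enumerate(ORDINAL_CATEGORIES)}

CATEGORY_CODE: dict[str, int] = {c: i + 1 for i, c in enumerate(CATEGORIES)}
CODE_CATEGORY: dict[int, str] = {v: k for k, v in CATEGORY_CODE.items()}

#: Tool codes used by the assessment-file dialect.
METHOD_CODE: dict[str, int] = {"WHO-UMC": 1, "LCAT": 2}
CODE_METHOD: dict[int, str] = {v: k for k, v in METHOD_CODE.items()}
METHODS: tuple[str, str] = ("WHO-UMC", "LCAT")

UNASSESSABLE = "unassessable"


def ordinal_distance(a: str, b: str) -> int | None:
    """Distance on the 1..4 causality scale; ``None`` if either is unranked."""
    ra, rb = ORDINAL_RANK.get(a), ORDINAL_RANK.get(b)
    if ra is None or rb is None:
        return None
    return abs(ra - rb)


def format_estimate(x: float) -> str:
    """Report rounding: two significant figures below 0.1, two decimals
    otherwise; halves round away from zero, matching the printed style."""
    import decimal
    import math

    if x != x:  # NaN
        return "undefined"
    if x == 0:
        return "0.00"
    d = decimal.Decimal(repr(float(x)))
    if abs(x) < 0.1:
        exponent = math.floor(math.log10(abs(x)))
        quantum = decimal.Decimal(1).scaleb(exponent - 1)
    else:
        quantum = decimal.Decimal("0.01")
    return str(d.quantize(quantum, rounding=decimal.ROUND_HALF_UP))
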