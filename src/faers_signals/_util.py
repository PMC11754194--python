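"""Small shared helpers: display rounding and numeric-aware key ordering."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (half-up), as printed tables do.

    Python's builtin ``round`` is banker's rounding; report tables in
    pharmacovigilance conventionally round 0.005 up to 0.01.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(count: int, total: int, ndigits: int = 2) -> float:
    """Percentage of ``count`` over ``total``, half-up to ``ndigits``."""
    if total == 0:
        return float("nan")
    return round_half_up(100.0 * count / total, ndigits)


def id_sort_key(value: str):
    """Order FAERS identifiers numerically when all-digit, else lexicographically.

    All-digit identifiers sort before (below) non-numeric ones so that a mixed
    group still has a deterministic maximum.
    """
    s = str(value)
    if s.isdigit():
        return (0, int(s), "")
    return (1, 0, s)
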