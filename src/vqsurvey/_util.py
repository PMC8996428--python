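"""Small shared helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as printed summary tables conventionally do.

    Python's round() is banker's rounding; percentage tables in the field round
    half up (66.35 -> 66.4), so all reported percentages go through this.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(part: int, total: int, ndigits: int = 1) -> float:
    if total == 0:
        return 0.0
    return round_half_up(100.0 * part / total, ndigits)
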