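"""Small shared helpers: rounding, complements, coordinate conversion."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, matching printed-report conventions.

    Python's builtin round() is banker's rounding; percentages in reports
    are conventionally rounded half-up (2.225 -> 2.23).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def to_bed_interval(start_1: int, end_1: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open (BED on disk)."""
    return start_1 - 1, end_1


def from_bed_interval(start_0: int, end_0: int) -> tuple[int, int]:
    """0-based half-open (BED on disk) -> 1-based inclusive."""
    return start_0 + 1, end_0
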