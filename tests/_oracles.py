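"""Independent reference implementations used only to cross-check results.

Each oracle is written directly from the defining recurrence or by
exhaustive enumeration, deliberately sharing no code with the package.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def encode(seq: str) -> np.ndarray:
    return np.array([_CODE[c] for c in seq.upper()], dtype=np.int8)


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq.upper()))


@njit(cache=False)
def _sw_score(a, b, match, mismatch, gap_open, gap_extend):
    """Smith-Waterman best local score, affine gaps (first gap column
    costs gap_open, each further column gap_extend); code 4 (N) never
    matches anything."""
    n, m = len(a), len(b)
    neg = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), neg)
    F = np.full((n + 1, m + 1), neg)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(E[i, j - 1] + gap_extend, H[i, j - 1] + gap_open)
            F[i, j] = max(F[i - 1, j] + gap_extend, H[i - 1, j] + gap_open)
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != 4) else mismatch
            h = H[i - 1, j - 1] + s
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0.0:
                h = 0.0
            H[i, j] = h
            if h > best:
                best = h
    return best


def sw_best_score(
    query: str,
    subject: str,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = -5,
    gap_extend: int = -2,
) -> float:
    """Best Smith-Waterman local score over both subject strands."""
    q = encode(query)
    plus = _sw_score(q, encode(subject), match, mismatch, gap_open, gap_extend)
    minus = _sw_score(q, encode(rc(subject)), match, mismatch, gap_open, gap_extend)
    return max(plus, minus)


def binomial_threshold_oracle(p: float, n: int, alpha: float) -> int:
    """Smallest T with P(X >= T) <= alpha by exact tail enumeration.

    The pmf is accumulated iteratively from the binomial recurrence
    pmf(k+1) = pmf(k) * (n-k)/(k+1) * p/(1-p); suitable for moderate n
    and p where (1-p)^n does not underflow.
    """
    if p == 0.0:
        return 1
    q = 1.0 - p
    pmf = q**n
    assert pmf > 0.0, "oracle regime requires (1-p)^n representable"
    tail = 1.0
    ratio = p / q
    for t in range(0, n + 2):
        if tail <= alpha:
            return t
        tail -= pmf
        if t < n:
            pmf *= (n - t) / (t + 1) * ratio
    return n + 1


def _primitive(motif: str) -> bool:
    p = len(motif)
    return not any(p % d == 0 and motif == motif[:d] * (p // d) for d in range(1, p))


def ssr_oracle(seq: str, min_span: dict[int, int]) -> set[tuple[int, int, str]]:
    """All maximal perfect tandem repeats by exhaustive start/period
    extension, as (start, end, motif) 1-based tuples.

    Applies the same reporting rules as the detector, derived
    independently: primitive motif, per-period span threshold, N breaks
    runs, and a locus fully inside a smaller-period locus is dropped.
    Periods without a threshold entry are not reported.
    """
    seq = seq.upper()
    n = len(seq)
    raw: list[tuple[int, int, str]] = []  # 0-based [start, end] inclusive
    for p in sorted(min_span):
        if p > 6:
            continue
        for start in range(n - p):
            # maximality on the left
            if start > 0 and start + p <= n and seq[start - 1] == seq[start - 1 + p] and "N" not in seq[start - 1 : start + p]:
                continue
            if "N" in seq[start : start + p + 1]:
                continue
            end = start + p  # minimal tandem needs p+1 chars
            if seq[start] != seq[start + p]:
                continue
            while end + 1 < n and seq[end + 1] == seq[end + 1 - p] and seq[end + 1] != "N":
                end += 1
            motif = seq[start : start + p]
            if not _primitive(motif):
                continue
            if end - start + 1 >= min_span[p]:
                raw.append((start, end, motif))
    kept: list[tuple[int, int, str]] = []
    for s, e, m in sorted(raw, key=lambda t: len(t[2])):
        if any(
            len(km) < len(m) and ks <= s and e <= ke for ks, ke, km in kept
        ):
            continue
        kept.append((s, e, m))
    return {(s + 1, e + 1, m) for s, e, m in kept}
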