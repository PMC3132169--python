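"""Perfect microsatellite (SSR) detection and motif classification.

Finds all maximal perfect tandem repetitions of a primitive 1-6 bp motif
meeting per-period minimum span thresholds (di 16, tri 15, tetra 16,
penta 15, hexa 18 bp; no imperfections allowed).  Motifs are grouped
into canonical classes under rotation and reverse complement, e.g.
AG/GA/TC/CT all report as class "AG".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

from oakbes._util import revcomp, round_half_up
from oakbes.bes_io import BesRead

_DEFAULT_MIN_SPAN = {1: 10, 2: 16, 3: 15, 4: 16, 5: 15, 6: 18}


@dataclass(frozen=True)
class SsrLocus:
    """One maximal perfect tandem repeat (1-based inclusive coordinates).

    The trailing copy may be partial, so ``copy_number`` can be
    fractional; the motif is primitive (not itself a repetition of a
    shorter string).
    """

    seq_id: str
    start: int
    end: int
    motif: str

    @property
    def period(self) -> int:
        return len(self.motif)

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    @property
    def copy_number(self) -> float:
        return self.span / self.period

    @property
    def canonical(self) -> str:
        return canonical_class(self.motif)


@dataclass
class SsrParams:
    """Detection thresholds.

    ``min_span`` maps motif period to the minimum locus span in bp.
    Mononucleotide runs are always detected internally (they take
    precedence over longer-period calls inside them) but are excluded
    from the period 2-6 statistics unless ``report_mono`` is set.
    """

    min_span: dict[int, int] = field(default_factory=lambda: dict(_DEFAULT_MIN_SPAN))
    report_mono: bool = False

    def validate(self) -> None:
        if any(v <= 0 for v in self.min_span.values()):
            raise ValueError("min_span thresholds must be positive")


def _is_primitive(motif: str) -> bool:
    p = len(motif)
    for d in range(1, p):
        if p % d == 0 and motif == motif[:d] * (p // d):
            return False
    return True


def canonical_class(motif: str) -> str:
    """Lexicographically smallest rotation of the motif or its reverse
    complement — the field's standard motif equivalence class."""
    if not motif:
        raise ValueError("motif must be non-empty")
    motif = motif.upper()
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif {motif!r} has characters outside ACGT")
    rc = revcomp(motif)
    variants = [m[i:] + m[:i] for m in (motif, rc) for i in range(len(m))]
    return min(variants)


def _segment_ssrs(seg: str, offset: int, seq_id: str, params: SsrParams) -> list[SsrLocus]:
    """All maximal perfect repeats in an N-free segment.

    ``offset`` is the 0-based position of the segment in the parent
    sequence; returned coordinates are 1-based on the parent.
    """
    loci: list[SsrLocus] = []
    n = len(seg)
    for p in range(1, 7):
        if p not in params.min_span or n < p + 1:
            continue
        need = params.min_span[p]
        i = 0
        while i < n - p:
            if seg[i] != seg[i + p]:
                i += 1
                continue
            j = i
            while j < n - p and seg[j] == seg[j + p]:
                j += 1
            # tandem run covers seg[i .. j + p - 1]
            span = j - i + p
            motif = seg[i : i + p]
            if span >= need and _is_primitive(motif):
                loci.append(
                    SsrLocus(seq_id=seq_id, start=offset + i + 1, end=offset + j + p, motif=motif)
                )
            i = j + 1
    return loci


def find_perfect_ssrs(
    sequence: str, params: SsrParams | None = None, seq_id: str = "seq"
) -> list[SsrLocus]:
    """All maximal perfect tandem repeats with primitive period <= 6.

    Runs containing N are broken at the N.  A locus fully contained in a
    locus of smaller period is suppressed, so each position is reported
    under its smallest period; mononucleotide runs are dropped from the
    output unless ``params.report_mono``.
    """
    params = params or SsrParams()
    params.validate()
    sequence = sequence.upper()
    loci: list[SsrLocus] = []
    offset = 0
    for segment in sequence.split("N"):
        if len(segment) >= 2:
            loci.extend(_segment_ssrs(segment, offset, seq_id, params))
        offset += len(segment) + 1

    loci.sort(key=lambda L: (L.period, L.start))
    kept: list[SsrLocus] = []
    for locus in loci:
        contained = any(
            k.period < locus.period and k.start <= locus.start and locus.end <= k.end
            for k in kept
        )
        if not contained:
            kept.append(locus)
    if not params.report_mono:
        kept = [L for L in kept if L.period >= 2]
    kept.sort(key=lambda L: (L.start, L.period))
    return kept


def find_ssrs_in_reads(
    reads: Iterable[BesRead], params: SsrParams | None = None
) -> list[SsrLocus]:
    loci: list[SsrLocus] = []
    for r in reads:
        loci.extend(find_perfect_ssrs(r.sequence, params, seq_id=r.read_id))
    return loci


def ssr_summary(loci: list[SsrLocus], total_bp: int) -> dict:
    """Counts by period, canonical-class distribution, and frequencies.

    Frequencies are expressed both as kb of sequence per SSR and as SSRs
    per 100 kb.  Class fractions are normalized within each period.
    With zero loci the frequencies are reported as None, not an error.
    """
    if total_bp <= 0:
        raise ValueError("total_bp must be positive")
    n = len(loci)
    by_period: dict[int, int] = {}
    class_counts: dict[int, dict[str, int]] = {}
    for L in loci:
        by_period[L.period] = by_period.get(L.period, 0) + 1
        class_counts.setdefault(L.period, {})
        class_counts[L.period][L.canonical] = class_counts[L.period].get(L.canonical, 0) + 1
    class_fractions = {
        p: {
            cls: round_half_up(100.0 * c / by_period[p], 2)
            for cls, c in sorted(counts.items())
        }
        for p, counts in class_counts.items()
    }
    period_fractions = {
        p: round_half_up(100.0 * c / n, 2) for p, c in sorted(by_period.items())
    }
    return {
        "n_ssrs": n,
        "total_bp": total_bp,
        "counts_by_period": dict(sorted(by_period.items())),
        "period_fractions_pct": period_fractions,
        "class_counts": {p: dict(sorted(c.items())) for p, c in sorted(class_counts.items())},
        "class_fractions_pct": class_fractions,
        "kb_per_ssr": round(total_bp / 1000.0 / n, 2) if n else None,
        "ssrs_per_100kb": round(n * 1e5 / total_bp, 2) if n else None,
    }


def loci_tsv(loci: list[SsrLocus]) -> str:
    header = "seq_id\tstart\tend\tperiod\tmotif\tcanonical_class\tspan\tcopies\n"
    rows = [
        f"{L.seq_id}\t{L.start}\t{L.end}\t{L.period}\t{L.motif}\t{L.canonical}\t{L.span}\t{L.copy_number:.2f}"
        for L in loci
    ]
    return header + "\n".join(rows) + ("\n" if rows else "")


def summary_json(loci: list[SsrLocus], total_bp: int) -> str:
    summary = ssr_summary(loci, total_bp)
    summary["class_counts"] = {str(k): v for k, v in summary["class_counts"].items()}
    summary["class_fractions_pct"] = {
        str(k): v for k, v in summary["class_fractions_pct"].items()
    }
    summary["counts_by_period"] = {str(k): v for k, v in summary["counts_by_period"].items()}
    summary["period_fractions_pct"] = {
        str(k): v for k, v in summary["period_fractions_pct"].items()
    }
    return json.dumps(summary, indent=2)
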